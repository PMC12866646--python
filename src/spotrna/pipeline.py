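"""Stage orchestration: build-ref -> demux -> assign -> count -> validate.

Each stage consumes standard files, writes its artifact plus a JSON stage
summary, and is skipped on rerun when its summary already exists (unless
forced), so a partially failed run resumes at the failing stage.  Every
discarded read increments exactly one reason counter; stage summaries
conserve reads.

Demultiplexing here tags reads with their pixel and UMI *before*
alignment (a demux table keyed by read id, and optionally a re-named R2
FASTQ for an external aligner); feature counting then joins alignments
to the table.  The end result is the same gene-pixel matrix as tagging
the post-alignment BAM would give, since the join key is the read id
either way.
"""

from __future__ import annotations

import json
import logging
import multiprocessing
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pysam

from . import annotation as ann
from . import quantify
from .assignment import assign_alignments, fragment_from_alignment
from .barcode_calling import BarcodeWhitelist, PixelID, call_barcode, resolve_pixel
from .read_structure import ReadLayout, parse_read1
from .validation import validate_features, curate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "Stage"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run (JSON-serialisable)."""

    outdir: str
    fastq_r1: str = ""
    fastq_r2: str = ""
    sam: str = ""
    annotation_sources: list = field(default_factory=list)  # [(path, dialect)]
    whitelist_a: str = ""
    whitelist_b: str = ""
    layout: dict = field(default_factory=dict)
    # parameters
    max_edit: int = 2
    strand_policy: str = "same"
    merge_overlap: float = 0.9
    min_aligned_length: int = 20
    max_softclip_fraction: float = 0.5
    flank_mult: float = 1.0
    alpha: float = 0.05
    min_fold: float = 2.0
    min_reads: int = 5
    validate: bool = True
    threads: int = 1
    seed: int = 0
    demux_chunk_size: int = 10_000

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def check(self, stages: tuple[str, ...]) -> None:
        """Fail before any processing when referenced inputs are missing
        or parameters are out of range."""
        need = {
            "build-ref": [p for p, _ in self.annotation_sources],
            "demux": [self.fastq_r1, self.whitelist_a, self.whitelist_b],
            "assign": [self.sam],
            "count": [],
            "validate": [self.sam],
        }
        for stage in stages:
            for p in need.get(stage, []):
                if not p or not Path(p).exists():
                    raise FileNotFoundError(
                        f"stage {stage}: required input missing: {p!r}"
                    )
        if self.max_edit < 0 or self.threads < 1:
            raise ValueError("max_edit must be >= 0 and threads >= 1")
        if self.strand_policy not in ("same", "opposite", "both"):
            raise ValueError(f"bad strand_policy {self.strand_policy!r}")
        if not 0 < self.merge_overlap <= 1:
            raise ValueError("merge_overlap must be in (0, 1]")
        if "demux" in stages:
            ReadLayout.from_dict(self.layout)  # raises LayoutError if invalid


class Stage:
    """Bookkeeping for one stage: summary JSON name + skip-on-rerun."""

    def __init__(self, name: str, outdir: Path, force: bool):
        self.name = name
        self.summary_path = outdir / f"stage_{name.replace('-', '_')}.json"
        self.force = force

    @property
    def done(self) -> bool:
        return self.summary_path.exists() and not self.force

    def finish(self, counters: dict) -> None:
        with open(self.summary_path, "w") as fh:
            json.dump({"stage": self.name, **counters}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        logger.info("stage %s: %s", self.name, counters)


# ---------------------------------------------------------------------------
# demux: chunked so work can fan out over processes; per-read work is pure,
# so results are independent of the partitioning.

_WORKER: dict = {}


def _demux_init(layout_dict, wl_a_path, wl_b_path, max_edit):
    _WORKER["layout"] = ReadLayout.from_dict(layout_dict)
    _WORKER["wl"] = {
        "A": BarcodeWhitelist.from_file(wl_a_path, "A"),
        "B": BarcodeWhitelist.from_file(wl_b_path, "B"),
    }
    _WORKER["max_edit"] = max_edit


def _demux_chunk(chunk: list[tuple[str, str]]):
    layout = _WORKER["layout"]
    whitelists = _WORKER["wl"]
    max_edit = _WORKER["max_edit"]
    out = []
    for read_id, seq in chunk:
        parsed = parse_read1(seq, layout, read_id)
        if parsed.status != "ok":
            out.append((read_id, None, None, parsed.fail_reason))
            continue
        calls = {
            slot: call_barcode(parsed.barcode_windows.get(slot, ""),
                               whitelists[slot], max_edit)
            for slot in layout.barcode_slots
        }
        pixel, reason = resolve_pixel(calls, tuple(layout.barcode_slots))
        if pixel is None:
            out.append((read_id, None, None, reason))
        else:
            out.append((read_id, pixel, parsed.umi, ""))
    return out


def _iter_chunks(path, size):
    chunk = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            chunk.append((rec.name, rec.sequence))
            if len(chunk) >= size:
                yield chunk
                chunk = []
    if chunk:
        yield chunk


def stage_demux(cfg: PipelineConfig, outdir: Path) -> dict:
    """Parse R1, call barcodes, resolve pixels; write the demux table."""
    counters: dict[str, int] = {"total": 0, "demuxed": 0}
    table_path = outdir / "demux_table.tsv"
    init_args = (cfg.layout, cfg.whitelist_a, cfg.whitelist_b, cfg.max_edit)
    chunks = _iter_chunks(cfg.fastq_r1, cfg.demux_chunk_size)
    with open(table_path, "w") as table:
        table.write("read_id\tx\ty\tumi\n")
        if cfg.threads > 1:
            pool = multiprocessing.Pool(cfg.threads, _demux_init, init_args)
            try:
                results = pool.imap(_demux_chunk, chunks, chunksize=1)
                _write_demux(results, table, counters)
            finally:
                pool.close()
                pool.join()
        else:
            _demux_init(*init_args)
            _write_demux((_demux_chunk(c) for c in chunks), table, counters)
    counters["discarded"] = counters["total"] - counters["demuxed"]
    return counters


def _write_demux(result_chunks, table, counters):
    for chunk in result_chunks:
        for read_id, pixel, umi, reason in chunk:
            counters["total"] += 1
            if pixel is None:
                counters[reason] = counters.get(reason, 0) + 1
            else:
                counters["demuxed"] += 1
                table.write(f"{read_id}\t{pixel.x}\t{pixel.y}\t{umi}\n")


def load_demux_table(path) -> dict[str, tuple[PixelID, str]]:
    out: dict[str, tuple[PixelID, str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            read_id, x, y, umi = line.rstrip("\n").split("\t")
            out[read_id] = (PixelID(int(x), int(y)), umi)
    return out


# ---------------------------------------------------------------------------

def stage_build_ref(cfg: PipelineConfig, outdir: Path) -> dict:
    feats = ann.load_sources(cfg.annotation_sources)
    merged = ann.merge_similar(feats, cfg.merge_overlap)
    introns = ann.derive_introns(merged)
    all_feats = sorted(merged + introns,
                       key=lambda f: (f.chrom, f.start, f.end, f.record_kind,
                                      f.name))
    ann.write_merged_gtf(all_feats, outdir / "merged.gtf",
                         outdir / "features.tsv")
    kinds: dict[str, int] = {}
    for f in all_feats:
        kinds[f.record_kind] = kinds.get(f.record_kind, 0) + 1
    return {"loaded": len(feats), "merged": len(merged),
            "introns": len(introns), **{f"n_{k}": v for k, v in kinds.items()}}


def stage_assign(cfg: PipelineConfig, outdir: Path) -> dict:
    feats = ann.read_merged_gtf(outdir / "merged.gtf")
    index = ann.AnnotationIndex(feats)
    demux = load_demux_table(outdir / "demux_table.tsv")
    counters: dict[str, int] = {}
    out_path = outdir / "assignments.tsv"
    with open(out_path, "w") as fh:
        fh.write("read_id\tpixel\tumi\tfeature\tlayer\tscore\tstatus\n")
        for a in assign_alignments(
            cfg.sam, index, demux, cfg.strand_policy,
            cfg.min_aligned_length, cfg.max_softclip_fraction, counters,
        ):
            if a.status != "assigned":
                continue
            fh.write(f"{a.read_id}\t{a.pixel.key}\t{a.umi}\t{a.feature_name}"
                     f"\t{a.layer}\t{float(a.score):.6g}\tassigned\n")
    return counters


def _all_pixel_keys(cfg: PipelineConfig) -> list[str]:
    n_a = len(BarcodeWhitelist.from_file(cfg.whitelist_a, "A"))
    n_b = len(BarcodeWhitelist.from_file(cfg.whitelist_b, "B"))
    return [f"{x}x{y}" for x in range(1, n_a + 1) for y in range(1, n_b + 1)]


def _read_assignment_rows(path):
    from fractions import Fraction

    from .assignment import ReadAssignment

    with open(path) as fh:
        next(fh)
        for line in fh:
            read_id, pixel, umi, feature, layer, score, status = (
                line.rstrip("\n").split("\t"))
            x, _, y = pixel.partition("x")
            yield ReadAssignment(read_id, PixelID(int(x), int(y)), umi,
                                 feature, layer, Fraction(float(score)), status)


def stage_count(cfg: PipelineConfig, outdir: Path) -> dict:
    import pandas as pd

    sidecar = pd.read_csv(outdir / "features.tsv", sep="\t",
                          keep_default_na=False)
    meta = (sidecar[sidecar["record_kind"].isin(["exon", "intron"])]
            [["name", "rna_class"]].drop_duplicates("name").set_index("name"))
    matrix = quantify.dedup_and_count(
        _read_assignment_rows(outdir / "assignments.tsv"),
        _all_pixel_keys(cfg), meta)
    quantify.write_matrix(matrix, outdir, prefix="matrix_")
    return {"features": matrix.shape[0], "pixels": matrix.shape[1],
            "umis_exon": matrix.total("exon"),
            "umis_intron": matrix.total("intron")}


def _midpoints_from_sam(sam_path):
    """Span midpoints of primary alignments, keyed by (chrom, strand)."""
    mids: dict[tuple[str, str], list[int]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for name, length in zip(fh.references, fh.lengths):
            lengths[name] = length
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            frag = fragment_from_alignment(aln)
            s, e = frag.span
            mids.setdefault((frag.chrom, frag.strand), []).append((s + e) // 2)
    return {k: sorted(v) for k, v in mids.items()}, lengths


def stage_validate(cfg: PipelineConfig, outdir: Path) -> dict:
    feats = ann.read_merged_gtf(outdir / "merged.gtf")
    exonlike = [f for f in feats if f.record_kind == "exon"]
    mids, chrom_lengths = _midpoints_from_sam(cfg.sam)
    report = validate_features(
        exonlike, mids, chrom_lengths, cfg.flank_mult, cfg.alpha,
        cfg.min_fold, cfg.min_reads, all_features=exonlike)
    report.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    matrix = quantify.read_matrix(outdir, prefix="matrix_")
    curated = curate(matrix, report)
    quantify.write_matrix(curated, outdir, prefix="curated_")
    verdicts = report["verdict"].value_counts().to_dict()
    return {"tested": len(report), **{f"verdict_{k}": int(v)
                                      for k, v in verdicts.items()}}


_STAGES = {
    "build-ref": stage_build_ref,
    "demux": stage_demux,
    "assign": stage_assign,
    "count": stage_count,
    "validate": stage_validate,
}


def run_pipeline(cfg: PipelineConfig, stages: Optional[tuple[str, ...]] = None,
                 force: bool = False) -> dict:
    """Run the requested stages in order; returns all stage summaries.

    A completed stage (its summary JSON exists) is skipped unless
    ``force``.  Stage failure raises, leaving earlier artifacts in place.
    """
    if stages is None:
        stages = ("build-ref", "demux", "assign", "count")
        if cfg.validate:
            stages += ("validate",)
    cfg.check(stages)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(outdir / "config.json")
    summaries = {}
    for name in stages:
        stage = Stage(name, outdir, force)
        if stage.done:
            logger.info("stage %s: already complete, skipping", name)
            with open(stage.summary_path) as fh:
                summaries[name] = json.load(fh)
            continue
        counters = _STAGES[name](cfg, outdir)
        stage.finish(counters)
        summaries[name] = {"stage": name, **counters}
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summaries
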