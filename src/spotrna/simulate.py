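"""Synthetic ground-truthed datasets for the whole pipeline.

Generates, at toy scale, everything the pipeline consumes: a random
genome, a whole-RNA annotation split across three source dialects
(GENCODE-style genes, a miRBase-style small-RNA GTF with hairpins and
mature 5p/3p arms, and a BED6+class file of deliberately spurious
features), per-axis barcode whitelists, paired reads with planted pixels,
UMIs and features, and a ground-truth SAM produced by exact placement —
no external aligner involved.  Truth tables give the expected per-read
assignment and the exact expected exon/intron count matrices, so
pipeline output can be checked cell-for-cell.

Error processes are explicit knobs: per-read barcode substitution /
insertion / deletion rates, an antisense fraction (reads planted on the
wrong strand, expected unassigned under the same-strand policy), a
spliced fraction, and a PCR-duplicate fraction.  Spurious features
receive only uniformly scattered background reads, so depth-enrichment
validation should reject them while planted features pass.

One master seed drives named child streams (genome, annotation, grid,
reads, errors), so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation import Feature
from .barcode_calling import PixelID

__all__ = ["SimulationSpec", "SimulatedDataset", "simulate_dataset",
           "simulate_depth_features"]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


@dataclass
class SimulationSpec:
    """All knobs of the synthetic dataset; defaults are the standard
    fixture conditions (2 x 100 kb chromosomes, 20 spliced genes, 10
    miRNAs with both mature arms, a 16x16 pixel grid, 5 UMIs per planted
    (pixel, feature), error processes off)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 100_000
    # annotation
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: int = 200
    intron_length: int = 300
    n_mirnas: int = 10
    arm_length: int = 22
    loop_length: int = 26
    n_spurious: int = 4
    spurious_length: int = 60
    # spatial grid / read 1 layout
    n_barcodes_a: int = 16
    n_barcodes_b: int = 16
    barcode_length: int = 8
    umi_length: int = 6
    linker: str = "ACGT"
    flank: int = 2
    r1_tail: int = 6
    # reads
    pixels_per_feature: int = 24
    umis_per_pair: int = 5
    fragment_length: int = 60
    spliced_fraction: float = 0.2
    antisense_fraction: float = 0.05
    duplicate_fraction: float = 0.1
    small_read_length: int = 22
    # error processes
    barcode_sub_rate: float = 0.0
    barcode_ins_rate: float = 0.0
    barcode_del_rate: float = 0.0
    # validation background
    background_reads_per_spurious: int = 40

    def validate(self) -> None:
        numeric_floor = {
            "n_chroms": 1, "chrom_length": 1000, "n_genes": 0,
            "exons_per_gene": 1, "exon_length": 10, "intron_length": 0,
            "n_mirnas": 0, "arm_length": 10, "loop_length": 0,
            "n_spurious": 0, "spurious_length": 10, "n_barcodes_a": 1,
            "n_barcodes_b": 1, "barcode_length": 4, "umi_length": 1,
            "flank": 0, "r1_tail": 0, "pixels_per_feature": 1,
            "umis_per_pair": 1, "fragment_length": 10,
            "small_read_length": 10, "background_reads_per_spurious": 0,
        }
        for name, lo in numeric_floor.items():
            if getattr(self, name) < lo:
                raise ValueError(f"simulation spec: {name} must be >= {lo}")
        if self.fragment_length > self.exon_length:
            raise ValueError("simulation spec: fragment longer than an exon")
        if self.pixels_per_feature > self.n_barcodes_a * self.n_barcodes_b:
            raise ValueError("simulation spec: more pixels per feature than grid pixels")
        for rate in ("barcode_sub_rate", "barcode_ins_rate", "barcode_del_rate",
                     "spliced_fraction", "antisense_fraction", "duplicate_fraction"):
            if not 0 <= getattr(self, rate) <= 1:
                raise ValueError(f"simulation spec: {rate} outside [0, 1]")

    @property
    def layout_dict(self) -> dict:
        return {
            "segments": [
                {"kind": "barcode", "expected_length": self.barcode_length,
                 "slot_id": "A"},
                {"kind": "linker", "expected_length": len(self.linker),
                 "sequence": self.linker},
                {"kind": "barcode", "expected_length": self.barcode_length,
                 "slot_id": "B"},
                {"kind": "umi", "expected_length": self.umi_length,
                 "slot_id": "U"},
            ],
            "flank": self.flank,
        }


@dataclass
class _Read:
    """One simulated read with its planted truth."""

    read_id: str
    pixel: PixelID
    umi: str
    chrom: str
    strand: str            # alignment strand
    blocks: tuple[tuple[int, int], ...]
    feature: str           # expected assignment ("" = expected unassigned)
    layer: str
    corrupted: str = ""    # "", or "<slot>:<sub|ins|del>"
    antisense: bool = False
    r1: str = ""


@dataclass
class SimulatedDataset:
    outdir: Path
    paths: dict[str, str]
    layout: dict
    features: list  # planted annotation records (pre-merge ground truth)
    truth_reads: "object" = None        # pandas DataFrame
    truth_matrix: "object" = None       # pandas DataFrame
    truth_validation: "object" = None   # pandas DataFrame
    chrom_lengths: dict = field(default_factory=dict)


def _greedy_whitelist(rng: np.random.Generator, n: int, length: int,
                      min_dist: int = 4) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("cannot build whitelist; lower n or min_dist")
        cand = _rand_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, w)) >= min_dist for w in out):
            out.append(cand)
    return out


def _corrupt(rng: np.random.Generator, barcode: str, kind: str) -> str:
    pos = int(rng.integers(0, len(barcode)))
    if kind == "sub":
        new = str(rng.choice([b for b in "ACGT" if b != barcode[pos]]))
        return barcode[:pos] + new + barcode[pos + 1:]
    if kind == "ins":
        return barcode[:pos] + str(rng.choice(list("ACGT"))) + barcode[pos:]
    if kind == "del":
        return barcode[:pos] + barcode[pos + 1:]
    raise ValueError(kind)


class _Placer:
    """Sequential non-overlapping placement with clean gaps per chromosome."""

    def __init__(self, chrom_names: list[str], chrom_length: int,
                 start: int = 500, gap: int = 400):
        self.cursors = {c: start for c in chrom_names}
        self.length = chrom_length
        self.gap = gap
        self.names = chrom_names
        self._i = 0

    def place(self, span: int) -> tuple[str, int]:
        # round-robin over chromosomes
        for _ in range(len(self.names)):
            chrom = self.names[self._i % len(self.names)]
            self._i += 1
            cur = self.cursors[chrom]
            if cur + span + self.gap <= self.length:
                self.cursors[chrom] = cur + span + self.gap
                return chrom, cur
        raise ValueError(
            "simulation spec inconsistent: features do not fit on the genome"
        )


def _build_annotation(spec: SimulationSpec, rng: np.random.Generator):
    """Plant genes, miRNA hairpins with arms, and spurious features."""
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    placer = _Placer(chroms, spec.chrom_length)
    feats: list[Feature] = []

    for g in range(spec.n_genes):
        n_ex = spec.exons_per_gene
        span = n_ex * spec.exon_length + (n_ex - 1) * spec.intron_length
        chrom, start = placer.place(span)
        strand = "+" if rng.random() < 0.5 else "-"
        gene, tx = f"GENE{g + 1}", f"GENE{g + 1}.t1"
        feats.append(Feature(tx, "mRNA", chrom, start, start + span, strand,
                             "transcript", parent=gene))
        for k in range(n_ex):
            es = start + k * (spec.exon_length + spec.intron_length)
            feats.append(Feature(gene, "mRNA", chrom, es, es + spec.exon_length,
                                 strand, "exon", parent=tx))

    for m in range(spec.n_mirnas):
        span = 2 * spec.arm_length + spec.loop_length
        chrom, start = placer.place(span)
        strand = "+" if rng.random() < 0.5 else "-"
        hp = f"mir-{m + 1}"
        feats.append(Feature(hp, "miRNA", chrom, start, start + span, strand,
                             "transcript", parent=hp))
        feats.append(Feature(f"miR-{m + 1}-5p", "miRNA", chrom, start,
                             start + spec.arm_length, strand, "exon", parent=hp))
        feats.append(Feature(f"miR-{m + 1}-3p", "miRNA", chrom,
                             start + span - spec.arm_length, start + span,
                             strand, "exon", parent=hp))

    for s in range(spec.n_spurious):
        chrom, start = placer.place(spec.spurious_length)
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"SPUR{s + 1}"
        feats.append(Feature(f"{name}.t", "snoRNA", chrom, start,
                             start + spec.spurious_length, strand,
                             "transcript", parent=name))
        feats.append(Feature(name, "snoRNA", chrom, start,
                             start + spec.spurious_length, strand, "exon",
                             parent=f"{name}.t"))
    return chroms, feats


def _sample_pixels(rng: np.random.Generator, spec: SimulationSpec) -> list[PixelID]:
    total = spec.n_barcodes_a * spec.n_barcodes_b
    flat = rng.choice(total, size=spec.pixels_per_feature, replace=False)
    return [PixelID(int(f) // spec.n_barcodes_b + 1,
                    int(f) % spec.n_barcodes_b + 1) for f in sorted(flat)]


def _distinct_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    while len(seen) < n:
        seen.add(_rand_seq(rng, length))
    return sorted(seen)


def _plan_reads(spec: SimulationSpec, feats: list[Feature],
                rng: np.random.Generator) -> list[_Read]:
    """Plant molecules per (feature, pixel) and expand to reads."""
    exons_by_gene: dict[str, list[Feature]] = {}
    tx_by_gene: dict[str, Feature] = {}
    arms: list[Feature] = []
    spurious: list[Feature] = []
    for f in feats:
        if f.rna_class == "mRNA":
            if f.record_kind == "exon":
                exons_by_gene.setdefault(f.name, []).append(f)
            else:
                tx_by_gene[f.parent] = f
        elif f.rna_class == "miRNA" and f.record_kind == "exon":
            arms.append(f)
        elif f.rna_class == "snoRNA" and f.record_kind == "exon":
            spurious.append(f)

    reads: list[_Read] = []
    serial = 0

    def new_id() -> str:
        nonlocal serial
        serial += 1
        return f"r{serial:07d}"

    def add_molecule(pixel, umi, chrom, strand, blocks, feature, layer,
                     antisense=False):
        reads.append(_Read(new_id(), pixel, umi, chrom, strand, blocks,
                           feature if not antisense else "", layer,
                           antisense=antisense))
        if rng.random() < spec.duplicate_fraction:
            reads.append(_Read(new_id(), pixel, umi, chrom, strand, blocks,
                               feature if not antisense else "", layer,
                               antisense=antisense))

    frag = spec.fragment_length
    for gene in sorted(exons_by_gene):
        exons = sorted(exons_by_gene[gene], key=lambda e: e.start)
        tx = tx_by_gene[gene]
        # exon-layer molecules
        for pixel in _sample_pixels(rng, spec):
            for umi in _distinct_umis(rng, spec.umis_per_pair, spec.umi_length):
                antisense = rng.random() < spec.antisense_fraction
                strand = tx.strand if not antisense else (
                    "-" if tx.strand == "+" else "+")
                spliced = len(exons) > 1 and rng.random() < spec.spliced_fraction
                if spliced:
                    # uneven split so the larger-overlap exon wins the score
                    k = int(rng.integers(0, len(exons) - 1))
                    a, b = exons[k], exons[k + 1]
                    la = int(0.6 * frag)
                    lb = frag - la
                    blocks = ((a.end - la, a.end), (b.start, b.start + lb))
                else:
                    e = exons[int(rng.integers(0, len(exons)))]
                    s = e.start + int(rng.integers(0, e.length - frag + 1))
                    blocks = ((s, s + frag),)
                add_molecule(pixel, umi, tx.chrom, strand, blocks, gene,
                             "exon", antisense)
        # intron-layer molecules
        introns = [(exons[i].end, exons[i + 1].start)
                   for i in range(len(exons) - 1)
                   if exons[i + 1].start - exons[i].end >= frag]
        if introns:
            for pixel in _sample_pixels(rng, spec):
                for umi in _distinct_umis(rng, spec.umis_per_pair,
                                          spec.umi_length):
                    antisense = rng.random() < spec.antisense_fraction
                    strand = tx.strand if not antisense else (
                        "-" if tx.strand == "+" else "+")
                    i0, i1 = introns[int(rng.integers(0, len(introns)))]
                    s = i0 + int(rng.integers(0, (i1 - i0) - frag + 1))
                    add_molecule(pixel, umi, tx.chrom, strand,
                                 ((s, s + frag),), gene, "intron", antisense)

    for arm in sorted(arms, key=lambda a: a.name):
        for pixel in _sample_pixels(rng, spec):
            for umi in _distinct_umis(rng, spec.umis_per_pair, spec.umi_length):
                add_molecule(pixel, umi, arm.chrom, arm.strand,
                             ((arm.start, arm.end),), arm.name, "exon")

    # spurious: uniformly scattered background only
    rl = spec.small_read_length
    for f in sorted(spurious, key=lambda s: s.name):
        w = f.length  # flank_mult = 1 background geometry
        for _ in range(spec.background_reads_per_spurious):
            pixel = PixelID(int(rng.integers(1, spec.n_barcodes_a + 1)),
                            int(rng.integers(1, spec.n_barcodes_b + 1)))
            umi = _rand_seq(rng, spec.umi_length)
            mid = int(rng.integers(f.start - w, f.end + w))
            s = mid - rl // 2
            l_o = max(0, min(s + rl, f.end) - max(s, f.start))
            assigned = l_o > rl - l_o  # positive overlap score, sole candidate
            reads.append(_Read(
                f"b{len(reads):07d}", pixel, umi, f.chrom, f.strand,
                ((s, s + rl),), f.name if assigned else "", "exon"))
    return reads


def _apply_barcode_errors(spec: SimulationSpec, reads: list[_Read],
                          wl_a: list[str], wl_b: list[str],
                          rng: np.random.Generator) -> None:
    """Build each R1 string, optionally corrupting one barcode."""
    rates = np.array([spec.barcode_sub_rate, spec.barcode_ins_rate,
                      spec.barcode_del_rate])
    kinds = ("sub", "ins", "del")
    for read in reads:
        bca = wl_a[read.pixel.x - 1]
        bcb = wl_b[read.pixel.y - 1]
        u = rng.random()
        acc = 0.0
        chosen = None
        for kind, rate in zip(kinds, rates):
            acc += rate
            if u < acc:
                chosen = kind
                break
        if chosen is not None:
            slot = "A" if rng.random() < 0.5 else "B"
            if slot == "A":
                bca = _corrupt(rng, bca, chosen)
            else:
                bcb = _corrupt(rng, bcb, chosen)
            read.corrupted = f"{slot}:{chosen}"
        tail = _rand_seq(rng, spec.r1_tail)
        read.r1 = bca + spec.linker + bcb + read.umi + tail


def _cigar(blocks: tuple[tuple[int, int], ...]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_dataset(spec: SimulationSpec, outdir) -> SimulatedDataset:
    """Generate the full fixture dataset into ``outdir``.

    Writes genome FASTA, three annotation sources, whitelists, paired
    FASTQ, a ground-truth SAM (coordinate-sorted) and truth tables; see
    the module docstring.  A fixed ``spec.seed`` gives byte-identical
    files.
    """
    import pandas as pd

    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_genome, rng_annot, rng_grid, rng_reads, rng_err = (
        np.random.default_rng(s) for s in streams
    )

    chroms, feats = _build_annotation(spec, rng_annot)
    genome = {c: _rand_seq(rng_genome, spec.chrom_length) for c in chroms}
    wl_a = _greedy_whitelist(rng_grid, spec.n_barcodes_a, spec.barcode_length)
    wl_b = _greedy_whitelist(rng_grid, spec.n_barcodes_b, spec.barcode_length)

    reads = _plan_reads(spec, feats, rng_reads)
    _apply_barcode_errors(spec, reads, wl_a, wl_b, rng_err)

    paths = {k: str(outdir / v) for k, v in {
        "genome": "genome.fa", "genes_gtf": "genes.gtf",
        "smallrna_gtf": "smallrna.gtf", "spurious_bed": "spurious.bed",
        "whitelist_a": "whitelist_a.txt", "whitelist_b": "whitelist_b.txt",
        "fastq_r1": "reads_R1.fastq", "fastq_r2": "reads_R2.fastq",
        "sam": "aligned.sam", "truth_reads": "truth_reads.tsv",
        "truth_matrix": "truth_matrix.tsv",
        "truth_validation": "truth_validation.tsv",
        "spec": "simspec.json",
    }.items()}

    with open(paths["genome"], "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = genome[c]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    with open(paths["genes_gtf"], "w") as fh:
        for f in feats:
            if f.rna_class != "mRNA":
                continue
            if f.record_kind == "transcript":
                attrs = (f'gene_id "{f.parent}"; gene_name "{f.parent}"; '
                         f'gene_type "protein_coding"; transcript_id "{f.name}";')
            else:
                attrs = (f'gene_id "{f.name}"; gene_name "{f.name}"; '
                         f'gene_type "protein_coding"; transcript_id "{f.parent}";')
            fh.write("\t".join((f.chrom, "sim", f.record_kind, str(f.start + 1),
                                str(f.end), ".", f.strand, ".", attrs)) + "\n")

    with open(paths["smallrna_gtf"], "w") as fh:
        for f in feats:
            if f.rna_class != "miRNA":
                continue
            if f.record_kind == "transcript":
                ftype = "miRNA_primary_transcript"
                attrs = f'Name "{f.name}";'
            else:
                ftype = "miRNA"
                attrs = f'Name "{f.name}"; Derives_from "{f.parent}";'
            fh.write("\t".join((f.chrom, "sim", ftype, str(f.start + 1),
                                str(f.end), ".", f.strand, ".", attrs)) + "\n")

    with open(paths["spurious_bed"], "w") as fh:
        for f in feats:
            if f.rna_class == "snoRNA" and f.record_kind == "exon":
                fh.write("\t".join((f.chrom, str(f.start), str(f.end), f.name,
                                    "0", f.strand, "snoRNA")) + "\n")

    for path, wl in ((paths["whitelist_a"], wl_a), (paths["whitelist_b"], wl_b)):
        with open(path, "w") as fh:
            fh.write("\n".join(wl) + "\n")

    with open(paths["fastq_r1"], "w") as r1, open(paths["fastq_r2"], "w") as r2:
        for read in reads:
            frag = "".join(genome[read.chrom][s:e] for s, e in read.blocks)
            seq2 = frag if read.strand == "+" else _revcomp(frag)
            r1.write(f"@{read.read_id}\n{read.r1}\n+\n{'I' * len(read.r1)}\n")
            r2.write(f"@{read.read_id}\n{seq2}\n+\n{'I' * len(seq2)}\n")

    order = {c: i for i, c in enumerate(chroms)}
    with open(paths["sam"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in chroms:
            fh.write(f"@SQ\tSN:{c}\tLN:{spec.chrom_length}\n")
        for read in sorted(reads, key=lambda r: (order[r.chrom],
                                                 r.blocks[0][0], r.read_id)):
            flag = 16 if read.strand == "-" else 0
            frag = "".join(genome[read.chrom][s:e] for s, e in read.blocks)
            fh.write("\t".join((
                read.read_id, str(flag), read.chrom,
                str(read.blocks[0][0] + 1), "255", _cigar(read.blocks), "*",
                "0", "0", frag, "I" * len(frag))) + "\n")

    truth_reads = pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "pixel": [r.pixel.key for r in reads],
        "umi": [r.umi for r in reads],
        "feature": [r.feature for r in reads],
        "layer": [r.layer if r.feature else "" for r in reads],
        "status": ["assigned" if r.feature else "unassigned" for r in reads],
        "corrupted": [r.corrupted for r in reads],
        "antisense": [r.antisense for r in reads],
    })
    truth_reads.to_csv(paths["truth_reads"], sep="\t", index=False)

    molecules = {(r.pixel.key, r.feature, r.layer, r.umi)
                 for r in reads if r.feature}
    counts: dict[tuple[str, str, str], int] = {}
    for pk, feat, layer, _ in molecules:
        counts[(feat, pk, layer)] = counts.get((feat, pk, layer), 0) + 1
    truth_matrix = pd.DataFrame(
        [(f, p, l, n) for (f, p, l), n in sorted(counts.items())],
        columns=["feature", "pixel", "layer", "count"],
    )
    truth_matrix.to_csv(paths["truth_matrix"], sep="\t", index=False)

    val_rows = []
    for f in feats:
        if f.record_kind != "exon":
            continue
        if f.rna_class == "miRNA":
            val_rows.append((f.name, "valid"))
        elif f.rna_class == "snoRNA":
            val_rows.append((f.name, "invalid"))
    truth_validation = pd.DataFrame(val_rows, columns=["feature", "expected"])
    truth_validation.to_csv(paths["truth_validation"], sep="\t", index=False)

    with open(paths["spec"], "w") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SimulatedDataset(
        outdir=outdir, paths=paths, layout=spec.layout_dict, features=feats,
        truth_reads=truth_reads, truth_matrix=truth_matrix,
        truth_validation=truth_validation,
        chrom_lengths={c: spec.chrom_length for c in chroms},
    )


def simulate_depth_features(
    n_features: int,
    reads_per_feature: int,
    enrichment: float,
    seed: int,
    feature_length: int = 60,
    flank_mult: float = 1.0,
    rna_class: str = "snoRNA",
):
    """Isolated features with midpoints drawn at a known enrichment level.

    With ``enrichment == 1`` midpoints are uniform over feature+flanks
    (the null); with enrichment k the in-feature density is k times the
    flank density.  Returns (features, midpoints_by_key, chrom_lengths)
    ready for :func:`spotrna.validation.validate_features`.
    """
    rng = np.random.default_rng(seed)
    L = feature_length
    w = int(round(flank_mult * L))
    spacing = L + 4 * w  # keep neighbouring flanks disjoint
    chrom = "chrV"
    feats = []
    midpoints = []
    p_in = enrichment * L / (enrichment * L + 2 * w)
    for i in range(n_features):
        start = 1000 + i * spacing
        feats.append(Feature(f"F{i + 1}", rna_class, chrom, start, start + L,
                             "+", "exon", parent=f"F{i + 1}.t"))
        inside = rng.random(reads_per_feature) < p_in
        n_in = int(inside.sum())
        midpoints.extend(start + rng.integers(0, L, n_in))
        for m in rng.integers(0, 2 * w, reads_per_feature - n_in):
            midpoints.append(start - w + m if m < w else start + L + (m - w))
    chrom_len = 1000 + n_features * spacing + 10 * w
    return feats, {(chrom, "+"): sorted(int(m) for m in midpoints)}, {chrom: chrom_len}
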