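"""Whole-RNA annotation: multi-source ingestion, merging and indexing.

A single reference GTF rarely covers the full transcriptome at the
granularity whole-RNA quantification needs: mature miRNA arms (-5p/-3p),
isotype-codon tRNAs and several small-RNA classes come from specialised
sources.  This module normalises several annotation dialects into one
:class:`Feature` model with 0-based half-open coordinates, merges similar
records across sources into single entries, derives intron features from
transcript/exon structure, and builds a strand-aware interval index for
read assignment.

Coordinate conventions: GTF is 1-based closed and converted at the I/O
boundary; BED is already 0-based half-open.  Internally everything is
0-based half-open.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "RNA_CLASSES",
    "Feature",
    "AnnotationIndex",
    "AnnotationError",
    "load_sources",
    "merge_similar",
    "derive_introns",
    "write_merged_gtf",
    "read_merged_gtf",
]

RNA_CLASSES = (
    "mRNA",
    "lncRNA",
    "miRNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "scaRNA",
    "piRNA",
    "Y_RNA",
    "miscRNA",
    "other",
)

# gene_type / biotype strings -> internal RNA class
_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mrna": "mRNA",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
    "mirna": "miRNA",
    "trna": "tRNA",
    "rrna": "rRNA",
    "snorna": "snoRNA",
    "snrna": "snRNA",
    "scarna": "scaRNA",
    "pirna": "piRNA",
    "y_rna": "Y_RNA",
    "yrna": "Y_RNA",
    "misc_rna": "miscRNA",
    "miscrna": "miscRNA",
}


class AnnotationError(ValueError):
    """Malformed annotation input, reported with file and line number."""


@dataclass(frozen=True)
class Feature:
    """One strand-aware genomic feature.

    ``record_kind`` distinguishes countable records (``exon``, ``intron``)
    from structural ``transcript`` records used to derive introns.
    ``name`` is the feature key used for counting (gene symbol, mature
    miRNA arm such as ``miR-X-5p``, tRNA isotype-codon); exons of the same
    gene share a name.  ``parent`` links exons/introns to their transcript.
    ``source_rank`` records which input file the record came from (file
    order = priority when merging).
    """

    name: str
    rna_class: str
    chrom: str
    start: int
    end: int
    strand: str
    record_kind: str
    parent: str = ""
    source_rank: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"feature {self.name}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize_class(biotype: str) -> str:
    b = biotype.strip().lower()
    if b in _BIOTYPE_MAP:
        return _BIOTYPE_MAP[b]
    for cls in RNA_CLASSES:
        if b == cls.lower():
            return cls
    return "other"


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and '"' not in chunk:  # GFF3-ish key=value
            key, _, val = chunk.partition("=")
        else:
            key, _, val = chunk.partition(" ")
        attrs[key.strip()] = val.strip().strip('"')
    return attrs


def _gtf_records(path: str):
    """Yield (lineno, fields, attrs) for each non-comment GTF line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            yield lineno, fields, _parse_gtf_attributes(fields[8])


def _load_gtf(path: str, rank: int) -> list[Feature]:
    """GENCODE-dialect or generic GTF.

    Recognises ``transcript``/``exon`` rows plus miRBase-style
    ``miRNA_primary_transcript`` (hairpin -> transcript record) and
    ``miRNA`` (mature arm -> exon record named with its -5p/-3p suffix).
    ``gene`` rows are skipped: transcript/exon structure is what drives
    intron derivation and counting.
    """
    feats: list[Feature] = []
    for lineno, fields, attrs in _gtf_records(path):
        chrom, _source, ftype, start1, end1, _score, strand, _frame, _ = fields
        start = int(start1) - 1
        end = int(end1)
        biotype = (
            attrs.get("gene_type")
            or attrs.get("gene_biotype")
            or attrs.get("rna_class")
            or ""
        )
        gene = attrs.get("gene_name") or attrs.get("Name") or attrs.get("gene_id") or ""
        try:
            if ftype == "transcript":
                tx = attrs.get("transcript_id") or f"{gene}.t"
                feats.append(
                    Feature(tx, _normalize_class(biotype), chrom, start, end,
                            strand, "transcript", parent=gene, source_rank=rank)
                )
            elif ftype == "exon":
                tx = attrs.get("transcript_id") or f"{gene}.t"
                feats.append(
                    Feature(gene, _normalize_class(biotype), chrom, start, end,
                            strand, "exon", parent=tx, source_rank=rank)
                )
            elif ftype == "miRNA_primary_transcript":
                name = attrs.get("Name") or attrs.get("gene_id") or ""
                feats.append(
                    Feature(name, "miRNA", chrom, start, end, strand,
                            "transcript", parent=name, source_rank=rank)
                )
            elif ftype == "miRNA":
                # mature arm; Derives_from / parent names the hairpin
                name = attrs.get("Name") or attrs.get("gene_id") or ""
                parent = attrs.get("Derives_from") or attrs.get("parent") or ""
                feats.append(
                    Feature(name, "miRNA", chrom, start, end, strand,
                            "exon", parent=parent, source_rank=rank)
                )
            elif ftype == "tRNA":
                # GtRNAdb-style single-interval tRNA keyed by isotype-codon
                iso = attrs.get("isotype") or ""
                codon = attrs.get("anticodon") or attrs.get("codon") or ""
                name = attrs.get("Name") or (
                    f"tRNA-{iso}-{codon}" if iso and codon else attrs.get("gene_id", "")
                )
                tx = f"{name}.t"
                feats.append(Feature(tx, "tRNA", chrom, start, end, strand,
                                     "transcript", parent=name, source_rank=rank))
                feats.append(Feature(name, "tRNA", chrom, start, end, strand,
                                     "exon", parent=tx, source_rank=rank))
            # gene rows and anything else: structural duplicates, skipped
        except AnnotationError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return feats


def _load_bed6(path: str, rank: int) -> list[Feature]:
    """BED6 with an RNA-class column 7; one exon-kind feature per line,
    plus a same-span transcript so every exon has a parent."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise AnnotationError(
                    f"{path}:{lineno}: BED6+class needs >= 7 columns"
                )
            chrom, start, end, name, _score, strand, cls = fields[:7]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            rna_class = _normalize_class(cls)
            tx = f"{name}.t"
            try:
                feats.append(Feature(tx, rna_class, chrom, start_i, end_i,
                                     strand, "transcript", parent=name,
                                     source_rank=rank))
                feats.append(Feature(name, rna_class, chrom, start_i, end_i,
                                     strand, "exon", parent=tx,
                                     source_rank=rank))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return feats


_DIALECTS = {
    "gencode": _load_gtf,
    "gtf": _load_gtf,
    "bed6": _load_bed6,
}


def load_sources(sources: Sequence[tuple[str, str]]) -> list[Feature]:
    """Load and normalise multiple annotation sources.

    ``sources`` is an ordered list of ``(path, dialect)``; the order sets
    merge priority (earlier files win naming).  Dialects: ``gencode``,
    ``gtf``, ``bed6``.
    """
    feats: list[Feature] = []
    for rank, (path, dialect) in enumerate(sources):
        loader = _DIALECTS.get(dialect)
        if loader is None:
            raise AnnotationError(
                f"unknown annotation dialect {dialect!r} for {path}"
            )
        loaded = loader(str(path), rank)
        if not loaded:
            logger.warning("annotation source %s is empty", path)
        feats.extend(loaded)
    return feats


def _reciprocal_overlap(a: Feature, b: Feature) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_similar(
    features: Sequence[Feature], min_reciprocal_overlap: float = 0.9
) -> list[Feature]:
    """Collapse similar records from different sources into single entries.

    Two features are similar iff they share rna_class, strand, chrom and
    record_kind and overlap reciprocally by at least the threshold.
    Similar sets (transitive closure) merge to one feature spanning the
    union interval; the name and parent come from the highest-priority
    (lowest source_rank) member.  Order-insensitive given ranks.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    groups: dict[tuple, list[Feature]] = defaultdict(list)
    for f in features:
        groups[(f.rna_class, f.strand, f.chrom, f.record_kind)].append(f)

    merged: list[Feature] = []
    n_merged_per_class: dict[str, int] = defaultdict(int)
    for key, group in groups.items():
        group = sorted(group, key=lambda f: (f.start, f.end, f.source_rank, f.name))
        parent_idx = list(range(len(group)))

        def find(i: int) -> int:
            while parent_idx[i] != i:
                parent_idx[i] = parent_idx[parent_idx[i]]
                i = parent_idx[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent_idx[rj] = ri

        # sweep: sorted by start, only nearby candidates can overlap
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].start >= group[i].end:
                    break
                if _reciprocal_overlap(group[i], group[j]) >= min_reciprocal_overlap:
                    union(i, j)

        comps: dict[int, list[Feature]] = defaultdict(list)
        for i, f in enumerate(group):
            comps[find(i)].append(f)
        for members in comps.values():
            if len(members) == 1:
                merged.append(members[0])
                continue
            rep = min(members, key=lambda f: (f.source_rank, f.name))
            merged.append(
                replace(
                    rep,
                    start=min(f.start for f in members),
                    end=max(f.end for f in members),
                )
            )
            n_merged_per_class[key[0]] += len(members) - 1
    for cls, n in sorted(n_merged_per_class.items()):
        logger.info("merged %d duplicate %s records", n, cls)
    return sorted(merged, key=lambda f: (f.chrom, f.start, f.end, f.name))


def derive_introns(features: Sequence[Feature]) -> list[Feature]:
    """Derive intron features from transcript/exon structure.

    Per transcript, introns are the transcript interval minus the union of
    its exons, one feature per gap.  Intron features are named after the
    transcript's parent gene so intron evidence aggregates per gene in the
    count matrix's intron layer.
    """
    exons_by_tx: dict[str, list[Feature]] = defaultdict(list)
    for f in features:
        if f.record_kind == "exon":
            exons_by_tx[f.parent].append(f)

    introns: list[Feature] = []
    for f in features:
        if f.record_kind != "transcript":
            continue
        exons = sorted(exons_by_tx.get(f.name, []), key=lambda e: e.start)
        if not exons:
            continue
        for e in exons:
            if e.start < f.start or e.end > f.end:
                raise AnnotationError(
                    f"exon [{e.start},{e.end}) outside transcript {f.name} "
                    f"span [{f.start},{f.end})"
                )
        gene = f.parent or f.name
        cursor = f.start
        for e in exons:
            if e.start > cursor:
                introns.append(
                    Feature(gene, f.rna_class, f.chrom, cursor, e.start,
                            f.strand, "intron", parent=f.name,
                            source_rank=f.source_rank)
                )
            cursor = max(cursor, e.end)
        if cursor < f.end:
            introns.append(
                Feature(gene, f.rna_class, f.chrom, cursor, f.end, f.strand,
                        "intron", parent=f.name, source_rank=f.source_rank)
            )
    return introns


class AnnotationIndex:
    """Strand-aware interval index over features.

    Queries return every feature overlapping the interval by >= 1 base on
    the requested strand(s).  Only countable records (exon, intron) are
    indexed for assignment; transcript records are kept for lookup and
    validation.
    """

    def __init__(self, features: Iterable[Feature]):
        self.features: list[Feature] = list(features)
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.by_name: dict[str, list[Feature]] = defaultdict(list)
        for f in self.features:
            self.by_name[f.name].append(f)
            if f.record_kind in ("exon", "intron"):
                self._trees[(f.chrom, f.strand)].addi(f.start, f.end, f)

    def query(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[Feature]:
        """Countable features overlapping [start, end) on ``strand``
        (both strands when None)."""
        strands = ("+", "-") if strand is None else (strand,)
        out: list[Feature] = []
        for s in strands:
            tree = self._trees.get((chrom, s))
            if tree is not None:
                out.extend(iv.data for iv in tree.overlap(start, end))
        return out

    def transcripts(self) -> list[Feature]:
        return [f for f in self.features if f.record_kind == "transcript"]


# ---------------------------------------------------------------------------
# merged-annotation I/O: single GTF (1-based closed) + sidecar feature table

def write_merged_gtf(features: Sequence[Feature], gtf_path, sidecar_path) -> None:
    """Write the merged annotation as GTF plus a TSV sidecar.

    The GTF feature column carries the record_kind; the sidecar holds
    (name, rna_class, record_kind, parent) for exact round-tripping.
    """
    with open(gtf_path, "w") as gtf:
        for f in features:
            attrs = (
                f'gene_name "{f.name}"; rna_class "{f.rna_class}"; '
                f'parent "{f.parent}";'
            )
            gtf.write(
                "\t".join(
                    (f.chrom, "spotrna", f.record_kind, str(f.start + 1),
                     str(f.end), ".", f.strand, ".", attrs)
                )
                + "\n"
            )
    with open(sidecar_path, "w") as tsv:
        tsv.write("name\trna_class\trecord_kind\tparent\n")
        seen = set()
        for f in features:
            row = (f.name, f.rna_class, f.record_kind, f.parent)
            if row not in seen:
                seen.add(row)
                tsv.write("\t".join(row) + "\n")


def read_merged_gtf(gtf_path) -> list[Feature]:
    """Read back a merged GTF written by :func:`write_merged_gtf`."""
    feats = []
    for lineno, fields, attrs in _gtf_records(str(gtf_path)):
        chrom, _src, kind, start1, end1, _score, strand, _frame, _ = fields
        feats.append(
            Feature(
                attrs.get("gene_name", ""),
                attrs.get("rna_class", "other"),
                chrom,
                int(start1) - 1,
                int(end1),
                strand,
                kind,
                parent=attrs.get("parent", ""),
            )
        )
    return feats
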