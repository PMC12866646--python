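"""Read-to-feature assignment by overlap score.

A fragment overlapping several annotations is assigned to the one with
the highest overlap score

    score = (L_o - L_no) / L_a

where L_o is the number of aligned fragment bases falling inside the
annotation, L_no = L_read - L_o is the number falling outside, and L_a is
the annotation length.  The score rewards containment (a fragment fully
inside a feature scores L_read/L_a) and penalises both partial overlap and
needlessly long features, which is what lets a mature miRNA arm out-score
both its hairpin precursor and a host-gene intron for a 22-nt fragment.

A read whose best score belongs to an exon record is exon evidence; to an
intron record, intron evidence.  Features tied at the maximal score make
the read multi-mapping: it is counted under a composite feature named by
plus-joining the tied names ("gene1+gene2+...+geneN").  Tie detection uses
exact rational arithmetic — floating point must not decide equality.

Only exon and derived-intron records compete; transcript records are
structural.  Candidates are collected per aligned block so a spliced
fragment does not pick up intron features spanning its skip gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Optional

import pysam

from .annotation import AnnotationIndex, Feature
from .barcode_calling import PixelID

__all__ = [
    "AlignedFragment",
    "ReadAssignment",
    "overlap_score",
    "assign_read",
    "fragment_from_alignment",
    "assign_alignments",
    "encode_read_name",
    "decode_read_name",
]

# reference-consuming, aligned CIGAR ops: M, D, =, X  (N splits blocks)
_ALIGNED_OPS = {0, 2, 7, 8}
_SKIP_OP = 3


@dataclass(frozen=True)
class AlignedFragment:
    """A primary alignment reduced to its aligned reference blocks.

    ``blocks`` are sorted, non-overlapping 0-based half-open intervals
    from match/deletion operations; splice skips (N) separate blocks.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    pixel: Optional[PixelID] = None
    umi: str = ""

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class ReadAssignment:
    """Per-read outcome: feature (or composite), layer and score."""

    read_id: str
    pixel: Optional[PixelID]
    umi: str
    feature_name: str
    layer: str
    score: Fraction
    status: str  # assigned | unassigned


def overlap_score(fragment: AlignedFragment, feature: Feature) -> Fraction:
    """Exact overlap score (L_o - L_no) / L_a of a fragment vs a feature."""
    l_o = 0
    for s, e in fragment.blocks:
        ov = min(e, feature.end) - max(s, feature.start)
        if ov > 0:
            l_o += ov
    l_no = fragment.aligned_length - l_o
    return Fraction(l_o - l_no, feature.length)


def assign_read(
    fragment: AlignedFragment,
    index: AnnotationIndex,
    strand_policy: str = "same",
) -> ReadAssignment:
    """Assign one fragment to its best-scoring overlapping feature.

    ``strand_policy``: ``same`` keeps features on the alignment strand
    (stranded whole-RNA libraries), ``opposite`` the reverse, ``both``
    ignores strand.  A read with no positive-scoring candidate is
    unassigned.  Ties at the maximum produce a composite multi-mapping
    name (sorted, deduplicated, plus-joined); the layer of a tie is exon
    if any tied feature is an exon, else intron.
    """
    if strand_policy == "same":
        strand: Optional[str] = fragment.strand
    elif strand_policy == "opposite":
        strand = "-" if fragment.strand == "+" else "+"
    elif strand_policy == "both":
        strand = None
    else:
        raise ValueError(f"unknown strand policy {strand_policy!r}")

    candidates: dict[int, Feature] = {}
    for s, e in fragment.blocks:
        for f in index.query(fragment.chrom, s, e, strand):
            candidates[id(f)] = f

    best: Optional[Fraction] = None
    winners: list[Feature] = []
    for f in candidates.values():
        score = overlap_score(fragment, f)
        if score <= 0:
            continue
        if best is None or score > best:
            best, winners = score, [f]
        elif score == best:
            winners.append(f)

    if best is None:
        return ReadAssignment(
            fragment.read_id, fragment.pixel, fragment.umi, "", "",
            Fraction(0), "unassigned",
        )
    names = sorted({f.name for f in winners})
    layer = "exon" if any(f.record_kind == "exon" for f in winners) else "intron"
    return ReadAssignment(
        fragment.read_id, fragment.pixel, fragment.umi, "+".join(names),
        layer, best, "assigned",
    )


# ---------------------------------------------------------------------------
# pixel/UMI metadata carried in read names: "<origname>|PX:<x>x<y>|UMI:<umi>"

def encode_read_name(name: str, pixel: PixelID, umi: str) -> str:
    return f"{name}|PX:{pixel.x}x{pixel.y}|UMI:{umi}"


def decode_read_name(qname: str) -> tuple[str, Optional[PixelID], str]:
    """Split a read name into (original name, pixel, umi); pixel is None
    when the name carries no metadata."""
    if "|PX:" not in qname:
        return qname, None, ""
    parts = qname.split("|")
    name = parts[0]
    pixel: Optional[PixelID] = None
    umi = ""
    for p in parts[1:]:
        if p.startswith("PX:"):
            x, _, y = p[3:].partition("x")
            pixel = PixelID(int(x), int(y))
        elif p.startswith("UMI:"):
            umi = p[4:]
    return name, pixel, umi


def fragment_from_alignment(
    aln: pysam.AlignedSegment,
    pixel: Optional[PixelID] = None,
    umi: str = "",
) -> AlignedFragment:
    """Build an AlignedFragment from a pysam record.

    Blocks merge consecutive M/D/=/X runs and split at N (splice skips);
    insertions and clips consume no reference and are ignored here.
    """
    blocks: list[tuple[int, int]] = []
    pos = aln.reference_start
    cur_start: Optional[int] = None
    for op, length in aln.cigartuples or ():
        if op in _ALIGNED_OPS:
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == _SKIP_OP:
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += length
        # I(1), S(4), H(5), P(6): no reference advance
    if cur_start is not None:
        blocks.append((cur_start, pos))
    name, name_pixel, name_umi = decode_read_name(aln.query_name)
    return AlignedFragment(
        read_id=name,
        chrom=aln.reference_name,
        strand="-" if aln.is_reverse else "+",
        blocks=tuple(blocks),
        pixel=pixel if pixel is not None else name_pixel,
        umi=umi or name_umi,
    )


def _soft_clip_fraction(aln: pysam.AlignedSegment) -> float:
    cig = aln.cigartuples or ()
    clipped = sum(length for op, length in cig if op == 4)
    total = sum(length for op, length in cig if op in (0, 1, 4, 7, 8))
    return clipped / total if total else 1.0


def assign_alignments(
    sam_path,
    index: AnnotationIndex,
    demux: Optional[dict[str, tuple[PixelID, str]]] = None,
    strand_policy: str = "same",
    min_aligned_length: int = 20,
    max_softclip_fraction: float = 0.5,
    counters: Optional[dict[str, int]] = None,
) -> Iterator[ReadAssignment]:
    """Stream assignments from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped so each
    fragment votes once.  Post-alignment filters drop fragments aligning
    fewer than ``min_aligned_length`` bases or soft-clipped beyond
    ``max_softclip_fraction``.  Pixel/UMI metadata comes from the read
    name or, failing that, from the ``demux`` table (read id ->
    (pixel, umi)); reads with neither are skipped as unbarcoded.
    ``counters`` (if given) accumulates per-category read counts.
    """
    c = counters if counters is not None else {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                c["unmapped"] = c.get("unmapped", 0) + 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                c["non_primary"] = c.get("non_primary", 0) + 1
                continue
            if _soft_clip_fraction(aln) > max_softclip_fraction:
                c["softclip_filtered"] = c.get("softclip_filtered", 0) + 1
                continue
            frag = fragment_from_alignment(aln)
            if frag.pixel is None and demux is not None:
                meta = demux.get(frag.read_id)
                if meta is not None:
                    frag = AlignedFragment(
                        frag.read_id, frag.chrom, frag.strand, frag.blocks,
                        pixel=meta[0], umi=meta[1],
                    )
            if frag.pixel is None:
                c["unbarcoded"] = c.get("unbarcoded", 0) + 1
                continue
            if frag.aligned_length < min_aligned_length:
                c["short_filtered"] = c.get("short_filtered", 0) + 1
                continue
            result = assign_read(frag, index, strand_policy)
            c[result.status] = c.get(result.status, 0) + 1
            yield result
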