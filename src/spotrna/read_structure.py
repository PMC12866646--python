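"""Parsing of read 1 into UMI and candidate spatial-barcode windows.

Read 1 of a DBiT-style spatial library carries an ordered arrangement of
spatial-barcode slots, fixed linker sequences and a UMI.  Because archival
(FFPE) material yields reads with insertions and deletions, barcode
segments are not excised at their nominal coordinates: each barcode window
is *expanded* by a configurable flank on both sides and the downstream
barcode caller resolves the identity with an indel-tolerant semi-global
match.  Linkers act as anchors: each linker is located by approximate
(substitution-only) search near its expected offset and subsequent segment
coordinates are taken relative to the located linker.

Reads are never error-corrected here; all recovery happens in barcode
calling.  Quality strings are carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Segment",
    "ReadLayout",
    "ParsedRead",
    "LayoutError",
    "parse_read1",
]

_SEGMENT_KINDS = frozenset({"barcode", "umi", "linker", "ignore"})


class LayoutError(ValueError):
    """Raised for an invalid read layout before any read is processed."""


@dataclass(frozen=True)
class Segment:
    """One element of the read-1 architecture.

    Parameters
    ----------
    kind:
        ``barcode``, ``umi``, ``linker`` or ``ignore``.
    expected_length:
        Nominal length in bases (>= 1).
    sequence:
        Literal bases; required for (and only for) linkers.
    slot_id:
        Identifier for barcode/UMI slots (e.g. ``"A"``, ``"B"``).
    """

    kind: str
    expected_length: int
    sequence: Optional[str] = None
    slot_id: Optional[str] = None


@dataclass(frozen=True)
class ReadLayout:
    """Declarative structure of read 1.

    ``flank`` is the number of bases of expansion added on each side of a
    barcode window to absorb indels upstream of the window; the default of
    2 covers up to two net inserted or deleted bases.  ``max_linker_mismatch``
    bounds the substitutions tolerated when anchoring a linker.
    """

    segments: tuple[Segment, ...]
    flank: int = 2
    max_linker_mismatch: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        self.validate()

    def validate(self) -> None:
        if not self.segments:
            raise LayoutError("layout has no segments")
        if self.flank < 0:
            raise LayoutError("flank must be >= 0")
        if self.max_linker_mismatch < 0:
            raise LayoutError("max_linker_mismatch must be >= 0")
        slot_ids = []
        n_umi = 0
        for seg in self.segments:
            if seg.kind not in _SEGMENT_KINDS:
                raise LayoutError(f"unknown segment kind {seg.kind!r}")
            if seg.expected_length < 1:
                raise LayoutError(
                    f"segment {seg.kind} has expected_length < 1"
                )
            if seg.kind == "linker":
                if not seg.sequence or len(seg.sequence) != seg.expected_length:
                    raise LayoutError(
                        "linker segment needs a literal sequence matching "
                        "expected_length"
                    )
            if seg.kind in ("barcode", "umi"):
                if not seg.slot_id:
                    raise LayoutError(f"{seg.kind} segment needs a slot_id")
                slot_ids.append(seg.slot_id)
            if seg.kind == "umi":
                n_umi += 1
        if len(set(slot_ids)) != len(slot_ids):
            raise LayoutError("slot_ids must be unique")
        if n_umi != 1:
            raise LayoutError("layout needs exactly one umi segment")
        if not any(s.kind == "barcode" for s in self.segments):
            raise LayoutError("layout needs at least one barcode segment")

    @property
    def barcode_slots(self) -> tuple[str, ...]:
        """Slot ids of barcode segments, in read order."""
        return tuple(
            s.slot_id for s in self.segments if s.kind == "barcode"
        )

    @property
    def umi_length(self) -> int:
        return next(s.expected_length for s in self.segments if s.kind == "umi")

    @property
    def min_length(self) -> int:
        """Minimum read length containing every segment at nominal size."""
        return sum(s.expected_length for s in self.segments)

    @classmethod
    def from_dict(cls, d: dict) -> "ReadLayout":
        """Build a layout from its JSON form (ordered segment list)."""
        segs = tuple(
            Segment(
                kind=s["kind"],
                expected_length=int(s["expected_length"]),
                sequence=s.get("sequence"),
                slot_id=s.get("slot_id"),
            )
            for s in d["segments"]
        )
        return cls(
            segments=segs,
            flank=int(d.get("flank", 2)),
            max_linker_mismatch=int(d.get("max_linker_mismatch", 1)),
        )

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    k: v
                    for k, v in (
                        ("kind", s.kind),
                        ("expected_length", s.expected_length),
                        ("sequence", s.sequence),
                        ("slot_id", s.slot_id),
                    )
                    if v is not None
                }
                for s in self.segments
            ],
            "flank": self.flank,
            "max_linker_mismatch": self.max_linker_mismatch,
        }


@dataclass
class ParsedRead:
    """Outcome of structural parsing of one read 1.

    ``barcode_windows`` maps slot id to the expanded window sequence;
    ``barcode_spans`` holds the un-expanded nominal spans, used only for
    diagnostics and property checks.
    """

    read_id: str
    umi: str = ""
    barcode_windows: dict[str, str] = field(default_factory=dict)
    barcode_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    status: str = "ok"
    fail_reason: str = ""


def _locate_linker(
    seq: str, linker: str, expected_at: int, radius: int, max_mismatch: int
) -> Optional[int]:
    """Best approximate occurrence of ``linker`` near ``expected_at``.

    Substitution-only comparison over candidate offsets within ``radius``
    of the expected offset; among minimal-mismatch candidates the one
    nearest the expected offset wins (leftmost on a distance tie).
    Returns the start offset, or None if no candidate has <= max_mismatch
    mismatches.
    """
    m = len(linker)
    best_mm = max_mismatch + 1
    best_off = None
    # candidates ordered by |offset - expected| then by offset
    offsets = sorted(
        range(max(0, expected_at - radius), expected_at + radius + 1),
        key=lambda o: (abs(o - expected_at), o),
    )
    for off in offsets:
        if off + m > len(seq):
            continue
        mm = sum(1 for a, b in zip(seq[off : off + m], linker) if a != b)
        if mm < best_mm:
            best_mm = mm
            best_off = off
            if mm == 0:
                break
    return best_off


def parse_read1(seq: str, layout: ReadLayout, read_id: str = "") -> ParsedRead:
    """Partition a read-1 sequence into UMI and expanded barcode windows.

    Segment coordinates start at the nominal layout offsets and are
    re-anchored after each located linker, so a single upstream indel
    shifts all downstream segments coherently.  Each barcode window is the
    nominal segment span widened by ``layout.flank`` bases on both sides,
    clipped to the read.

    Returns a :class:`ParsedRead` with ``status="structure_fail"`` and a
    ``fail_reason`` of ``"read_too_short"`` or ``"linker_not_found"`` when
    the structure cannot be resolved.
    """
    if not seq:
        return ParsedRead(read_id, status="structure_fail", fail_reason="read_too_short")
    if len(seq) < layout.min_length:
        return ParsedRead(read_id, status="structure_fail", fail_reason="read_too_short")

    out = ParsedRead(read_id)
    radius = layout.flank + 2
    pos = 0
    for seg in layout.segments:
        if seg.kind == "linker":
            off = _locate_linker(
                seq, seg.sequence, pos, radius, layout.max_linker_mismatch
            )
            if off is None:
                return ParsedRead(
                    read_id, status="structure_fail", fail_reason="linker_not_found"
                )
            pos = off + seg.expected_length
            continue
        start, end = pos, pos + seg.expected_length
        if seg.kind == "barcode":
            if start >= len(seq):
                return ParsedRead(
                    read_id, status="structure_fail", fail_reason="read_too_short"
                )
            lo = max(0, start - layout.flank)
            hi = min(len(seq), end + layout.flank)
            out.barcode_windows[seg.slot_id] = seq[lo:hi]
            out.barcode_spans[seg.slot_id] = (start, min(end, len(seq)))
        elif seg.kind == "umi":
            umi = seq[start:end]
            if len(umi) < seg.expected_length:
                return ParsedRead(
                    read_id, status="structure_fail", fail_reason="read_too_short"
                )
            out.umi = umi
        pos = end
    return out
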