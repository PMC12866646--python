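"""Resolution of expanded barcode windows to whitelist barcodes.

Every spatial barcode is pre-designed, so calling reduces to finding the
whitelist entry with the minimal semi-global edit distance to the window:
the barcode must be consumed in full while the window's flanks are free.
This makes the call indel-tolerant — an insertion or deletion upstream of
the barcode merely shifts it inside the expanded window at no cost.

Only the best match is retained.  If two or more whitelist entries attain
the same minimal distance the read is ambiguous and discarded; there is no
tie-breaking.  With ``max_edit=0`` only exact-substring occurrences are
assigned.

The semi-global distances are computed with edlib (infix mode); an
exact-substring prefilter short-circuits the scan for error-free windows,
which are the overwhelming majority, without changing any call: a
distance-0 hit can only be an exact occurrence, and the prefilter
enumerates all of those.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

__all__ = [
    "BarcodeWhitelist",
    "BarcodeCall",
    "PixelID",
    "call_barcode",
    "resolve_pixel",
]


@dataclass(frozen=True)
class PixelID:
    """Spatial pixel addressed by the (barcode-A, barcode-B) index pair."""

    x: int
    y: int

    @property
    def key(self) -> str:
        return f"{self.x}x{self.y}"


@dataclass(frozen=True)
class BarcodeCall:
    """Outcome of matching one window against one whitelist.

    ``status`` is ``assigned`` (unique best match within ``max_edit``),
    ``ambiguous`` (>= 2 entries tie at the minimal distance) or
    ``unmatched`` (minimal distance exceeds ``max_edit``).
    ``barcode_index`` and ``edit_distance`` are set for assigned calls only.
    """

    slot_id: str
    status: str
    barcode_index: Optional[int] = None
    edit_distance: Optional[int] = None


class BarcodeWhitelist:
    """Ordered list of valid barcodes for one slot; line order = index.

    Indices are 1-based and contiguous; all sequences must share one
    length and be unique within the slot.
    """

    def __init__(self, slot_id: str, sequences: Iterable[str]):
        self.slot_id = slot_id
        self.sequences: tuple[str, ...] = tuple(
            s.strip().upper() for s in sequences
        )
        if not self.sequences:
            raise ValueError(f"whitelist {slot_id}: empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"whitelist {slot_id}: sequences of unequal length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError(f"whitelist {slot_id}: duplicate sequences")
        self.barcode_length = lengths.pop()
        # exact-match lookup: sequence -> 1-based index
        self._exact = {s: i + 1 for i, s in enumerate(self.sequences)}

    def __len__(self) -> int:
        return len(self.sequences)

    def index_of(self, sequence: str) -> Optional[int]:
        return self._exact.get(sequence)

    @classmethod
    def from_file(cls, path, slot_id: str) -> "BarcodeWhitelist":
        with open(path) as fh:
            seqs = [line.strip() for line in fh if line.strip()]
        return cls(slot_id, seqs)


def _exact_hits(window: str, whitelist: BarcodeWhitelist) -> set[int]:
    """1-based indices of whitelist barcodes occurring verbatim in window."""
    L = whitelist.barcode_length
    hits: set[int] = set()
    for off in range(len(window) - L + 1):
        idx = whitelist._exact.get(window[off : off + L])
        if idx is not None:
            hits.add(idx)
    return hits


def semi_global_distance(barcode: str, window: str) -> int:
    """Minimal edit distance of ``barcode`` aligned anywhere inside ``window``.

    The barcode is fully consumed; window bases outside the alignment are
    free (edlib infix/"HW" mode).
    """
    return edlib.align(barcode, window, mode="HW", task="distance")["editDistance"]


def call_barcode(
    window: str, whitelist: BarcodeWhitelist, max_edit: int = 2
) -> BarcodeCall:
    """Resolve one expanded window to its best whitelist barcode.

    Returns ``assigned`` with the unique minimizer when the minimal
    semi-global distance is <= ``max_edit`` and unique, ``ambiguous`` when
    tied, ``unmatched`` otherwise.  A window shorter than
    ``barcode_length - max_edit`` cannot contain the barcode and is
    unmatched, not an error.
    """
    if max_edit < 0:
        raise ValueError("max_edit must be >= 0")
    slot = whitelist.slot_id
    if not window or len(window) < whitelist.barcode_length - max_edit:
        return BarcodeCall(slot, "unmatched")

    hits = _exact_hits(window, whitelist)
    if len(hits) == 1:
        return BarcodeCall(slot, "assigned", hits.pop(), 0)
    if len(hits) > 1:
        return BarcodeCall(slot, "ambiguous")

    best = max_edit + 1
    minimizers: list[int] = []
    for i, bc in enumerate(whitelist.sequences):
        d = edlib.align(bc, window, mode="HW", task="distance", k=best)[
            "editDistance"
        ]
        if d < 0:  # beyond current bound k
            continue
        if d < best:
            best = d
            minimizers = [i + 1]
        elif d == best:
            minimizers.append(i + 1)
    if not minimizers or best > max_edit:
        return BarcodeCall(slot, "unmatched")
    if len(minimizers) > 1:
        return BarcodeCall(slot, "ambiguous")
    return BarcodeCall(slot, "assigned", minimizers[0], best)


def resolve_pixel(
    calls: dict[str, BarcodeCall], slot_order: tuple[str, str] = ("A", "B")
) -> tuple[Optional[PixelID], str]:
    """Compose per-slot calls into a pixel coordinate.

    ``slot_order`` names the (x, y) slots; x is always the first slot, y
    the second.  Returns ``(PixelID, "")`` when every slot is assigned,
    otherwise ``(None, reason)`` where the reason names the first failing
    slot, e.g. ``"barcode_B_ambiguous"``.
    """
    for slot in slot_order:
        call = calls.get(slot)
        if call is None:
            return None, f"barcode_{slot}_missing"
        if call.status != "assigned":
            return None, f"barcode_{slot}_{call.status}"
    return (
        PixelID(calls[slot_order[0]].barcode_index, calls[slot_order[1]].barcode_index),
        "",
    )
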