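"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the semi-global
edit distance is a full dynamic-programming table, and the assignment
oracle scores every feature exhaustively with exact rationals.
"""

from __future__ import annotations

from fractions import Fraction


def semi_global_dp(query: str, target: str) -> int:
    """Edit distance of ``query`` aligned anywhere inside ``target``:
    query fully consumed, target flanks free (row 0 all zero, answer is
    the minimum of the last row)."""
    n = len(target)
    prev = [0] * (n + 1)
    for i, qc in enumerate(query, 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j - 1] + (qc != target[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)


def call_barcode_oracle(window: str, sequences, max_edit: int):
    """Exhaustive best-match call: (status, index, distance)."""
    dists = [(semi_global_dp(bc, window), i + 1) for i, bc in enumerate(sequences)]
    best = min(d for d, _ in dists)
    winners = [i for d, i in dists if d == best]
    if best > max_edit:
        return ("unmatched", None, None)
    if len(winners) > 1:
        return ("ambiguous", None, None)
    return ("assigned", winners[0], best)


def assign_oracle(fragment, features, strand_policy: str = "same"):
    """Exhaustive overlap-score winner: (composite name, layer, score) or
    None when no candidate scores positive.  Scores use the equivalent
    form (2*L_o - L_read)/L_a with exact rationals."""
    cands = []
    for f in features:
        if f.record_kind not in ("exon", "intron") or f.chrom != fragment.chrom:
            continue
        if strand_policy == "same" and f.strand != fragment.strand:
            continue
        if strand_policy == "opposite" and f.strand == fragment.strand:
            continue
        if not any(min(e, f.end) > max(s, f.start) for s, e in fragment.blocks):
            continue
        l_o = sum(
            max(0, min(e, f.end) - max(s, f.start)) for s, e in fragment.blocks
        )
        score = Fraction(2 * l_o - fragment.aligned_length, f.length)
        if score > 0:
            cands.append((score, f))
    if not cands:
        return None
    best = max(s for s, _ in cands)
    winners = [f for s, f in cands if s == best]
    names = sorted({f.name for f in winners})
    layer = "exon" if any(f.record_kind == "exon" for f in winners) else "intron"
    return ("+".join(names), layer, best)


def bh_stepup(pvals, alpha: float = 0.05):
    """Reference Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj
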