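"""Depth-enrichment validation of annotated features.

Whole-RNA references compiled from many databases inevitably carry
entries that are not expressed in a given tissue; randomly fragmented
background RNA can still deposit reads on them and inflate the matrix
with spurious features.  A genuine compact RNA (a mature miRNA arm, a
tRNA, a snoRNA) shows a read-depth step: markedly more reads inside the
annotation than in its flanking background.

The test here formalises that principle with midpoint counting: each
same-strand alignment is one trial, landing inside the feature (success)
or in its flanks (failure).  Under no enrichment, midpoints fall
uniformly, so in-feature landings are Binomial(n, p0) with
p0 = L_in / (L_in + L_bg).  The p-value is the one-sided exact binomial
tail P(X >= in_count); q-values are Benjamini-Hochberg across features.
A feature is valid when q <= alpha, fold enrichment >= min_fold and
in_count >= min_reads.  Flank bases covered by any other same-strand
feature are masked out of the background so a neighbour's real signal
cannot masquerade as background.

Validation runs on pseudo-bulk (all pixels pooled): per-pixel depths in
degraded material are far too sparse to test, and a feature's verdict
then filters every pixel column identically.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .annotation import Feature
from .quantify import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DepthProfile",
    "ValidationResult",
    "SMALL_RNA_CLASSES",
    "profile_feature",
    "enrichment_test",
    "validate_features",
    "curate",
]

# classes the depth-step logic targets: compact structures shorter than or
# comparable to the fragment length
SMALL_RNA_CLASSES = frozenset(
    {"miRNA", "tRNA", "snoRNA", "snRNA", "scaRNA", "piRNA", "Y_RNA", "miscRNA"}
)


@dataclass(frozen=True)
class DepthProfile:
    """Midpoint counts inside a feature vs its flanking background."""

    name: str
    in_count: int
    bg_count: int
    l_in: int
    l_bg: int

    @property
    def testable(self) -> bool:
        return self.l_bg > 0 and (self.in_count + self.bg_count) > 0


@dataclass
class ValidationResult:
    name: str
    in_count: int
    bg_count: int
    l_in: int
    l_bg: int
    fold_enrichment: float
    p_value: Optional[float]
    q_value: Optional[float] = None
    verdict: str = "untestable"


def _subtract_intervals(
    windows: list[tuple[int, int]], masks: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Remove masked spans from windows; all half-open intervals."""
    out = []
    for ws, we in windows:
        cur = ws
        for ms, me in sorted(masks):
            if me <= cur or ms >= we:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= we:
                break
        if cur < we:
            out.append((cur, we))
    return [(s, e) for s, e in out if e > s]


def profile_feature(
    feature: Feature,
    midpoints: Sequence[int],
    flank_mult: float = 1.0,
    chrom_length: Optional[int] = None,
    neighbors: Sequence[Feature] = (),
) -> DepthProfile:
    """Count alignment midpoints inside a feature vs its background flanks.

    ``midpoints`` are the sorted midpoint coordinates of same-strand,
    same-chromosome alignments.  Background = one upstream plus one
    downstream window, each ``flank_mult`` x feature length, clipped at
    chromosome bounds and with bases covered by any other same-strand
    ``neighbors`` feature masked out (reducing L_bg).
    """
    if flank_mult <= 0:
        raise ValueError("flank_mult must be > 0")
    L = feature.length
    w = int(round(flank_mult * L))
    up = (max(0, feature.start - w), feature.start)
    down_end = feature.end + w
    if chrom_length is not None:
        down_end = min(down_end, chrom_length)
    down = (feature.end, max(feature.end, down_end))

    masks = [
        (n.start, n.end)
        for n in neighbors
        if n.chrom == feature.chrom
        and n.strand == feature.strand
        and not (n.start == feature.start and n.end == feature.end and n.name == feature.name)
    ]
    bg_windows = _subtract_intervals([w_ for w_ in (up, down) if w_[1] > w_[0]], masks)
    l_bg = sum(e - s for s, e in bg_windows)

    mids = sorted(midpoints)

    def count_in(s: int, e: int) -> int:
        return bisect.bisect_left(mids, e) - bisect.bisect_left(mids, s)

    in_count = count_in(feature.start, feature.end)
    bg_count = sum(count_in(s, e) for s, e in bg_windows)
    return DepthProfile(feature.name, in_count, bg_count, L, l_bg)


def enrichment_test(profile: DepthProfile) -> ValidationResult:
    """One-sided exact binomial test of in-feature midpoint enrichment.

    p0 = L_in / (L_in + L_bg); p = P(X >= in_count | n, p0) with
    n = in_count + bg_count.  Fold enrichment is the ratio of in-feature
    to background midpoint densities (inf when the background is clean,
    0 when the feature is empty).  Untestable profiles (no background
    length or no reads at all) get no p-value.
    """
    if not profile.testable:
        return ValidationResult(
            profile.name, profile.in_count, profile.bg_count,
            profile.l_in, profile.l_bg, float("nan"), None,
        )
    n = profile.in_count + profile.bg_count
    p0 = profile.l_in / (profile.l_in + profile.l_bg)
    p = binomtest(profile.in_count, n, p0, alternative="greater").pvalue
    in_density = profile.in_count / profile.l_in
    if profile.bg_count == 0:
        fold = float("inf") if profile.in_count > 0 else 0.0
    else:
        fold = in_density / (profile.bg_count / profile.l_bg)
    return ValidationResult(
        profile.name, profile.in_count, profile.bg_count,
        profile.l_in, profile.l_bg, fold, float(p),
    )


def validate_features(
    features: Sequence[Feature],
    midpoints_by_key: dict[tuple[str, str], Sequence[int]],
    chrom_lengths: Optional[dict[str, int]] = None,
    flank_mult: float = 1.0,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    min_reads: int = 5,
    classes: Optional[Iterable[str]] = None,
    all_features: Optional[Sequence[Feature]] = None,
) -> pd.DataFrame:
    """Run the enrichment test over testable features and call verdicts.

    ``features``: countable records to test (exon-kind records of the
    selected RNA classes by default).  ``midpoints_by_key`` maps
    (chrom, strand) to sorted alignment midpoints.  ``all_features``
    supplies the neighbour set for background masking (defaults to
    ``features``).  Returns the validation report as a DataFrame with BH
    q-values and verdicts (valid | invalid | untestable).
    """
    classes = SMALL_RNA_CLASSES if classes is None else set(classes)
    neighbors = list(all_features if all_features is not None else features)
    results: list[ValidationResult] = []
    for f in features:
        if f.record_kind != "exon" or f.rna_class not in classes:
            continue
        mids = midpoints_by_key.get((f.chrom, f.strand), ())
        clen = (chrom_lengths or {}).get(f.chrom)
        prof = profile_feature(f, mids, flank_mult, clen, neighbors)
        results.append(enrichment_test(prof))

    tested = [r for r in results if r.p_value is not None]
    if tested:
        _, qvals, _, _ = multipletests(
            [r.p_value for r in tested], alpha=alpha, method="fdr_bh"
        )
        for r, q in zip(tested, qvals):
            r.q_value = float(q)
            ok = (
                r.q_value <= alpha
                and r.fold_enrichment >= min_fold
                and r.in_count >= min_reads
            )
            r.verdict = "valid" if ok else "invalid"
    return pd.DataFrame(
        {
            "feature": [r.name for r in results],
            "in_count": [r.in_count for r in results],
            "bg_count": [r.bg_count for r in results],
            "L_in": [r.l_in for r in results],
            "L_bg": [r.l_bg for r in results],
            "fold": [r.fold_enrichment for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "verdict": [r.verdict for r in results],
        }
    )


def curate(matrix: CountMatrix, results: pd.DataFrame) -> CountMatrix:
    """Drop invalid feature rows from the matrix; the uncurated matrix is
    left untouched for the caller.  Untestable features are kept.  An
    empty results table returns the matrix unchanged with a warning."""
    if results is None or len(results) == 0:
        logger.warning("curate: empty validation results; matrix unchanged")
        return matrix
    invalid = set(results.loc[results["verdict"] == "invalid", "feature"])
    return matrix.drop_features(invalid)
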