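"""Depth-enrichment validation: window arithmetic, exact binomial tails,
BH correction and matrix curation."""

import math

import numpy as np
import pytest

from spotrna.annotation import Feature
from spotrna.quantify import dedup_and_count
from spotrna.validation import (
    DepthProfile,
    curate,
    enrichment_test,
    profile_feature,
    validate_features,
)

from _oracles import bh_stepup
from test_quantify import PIXELS, asg


def feat(start, end, name="F", strand="+", cls="snoRNA"):
    return Feature(name, cls, "chr1", start, end, strand, "exon", parent=f"{name}.t")


class TestProfileFeature:
    def test_plain_flanks(self):
        p = profile_feature(feat(1000, 1100), [], flank_mult=1.0)
        assert (p.l_in, p.l_bg) == (100, 200)

    def test_chromosome_start_clips_upstream(self):
        p = profile_feature(feat(0, 100), [], flank_mult=1.0)
        assert p.l_bg == 100

    def test_neighbor_masking(self):
        neighbor = feat(1100, 1150, name="N")
        p = profile_feature(feat(1000, 1100), [], 1.0, neighbors=[neighbor])
        assert p.l_bg == 100 + 50

    def test_opposite_strand_neighbor_not_masked(self):
        neighbor = feat(1100, 1150, name="N", strand="-")
        p = profile_feature(feat(1000, 1100), [], 1.0, neighbors=[neighbor])
        assert p.l_bg == 200

    def test_midpoint_counting(self):
        mids = [999, 1000, 1050, 1099, 1100, 1150, 90000]
        p = profile_feature(feat(1000, 1100), mids, 1.0)
        assert (p.in_count, p.bg_count) == (3, 3)  # far midpoint uncounted


class TestEnrichmentTest:
    def test_zero_in_count_p_one(self):
        r = enrichment_test(DepthProfile("F", 0, 20, 100, 200))
        assert r.p_value == pytest.approx(1.0)

    def test_all_inside_closed_form(self):
        # p0 = 1/3, all 10 reads inside: p = (1/3)^10
        r = enrichment_test(DepthProfile("F", 10, 0, 100, 200))
        assert r.p_value == pytest.approx((1 / 3) ** 10, rel=1e-12)
        assert math.isinf(r.fold_enrichment)

    def test_binomial_tail_exact(self):
        # 8 of 10 inside at p0=1/3: sum_{k=8..10} C(10,k)(1/3)^k(2/3)^(10-k)
        expected = sum(
            math.comb(10, k) * (1 / 3) ** k * (2 / 3) ** (10 - k)
            for k in range(8, 11)
        )
        r = enrichment_test(DepthProfile("F", 8, 2, 100, 200))
        assert r.p_value == pytest.approx(expected, rel=1e-12)
        assert r.fold_enrichment == pytest.approx((8 / 100) / (2 / 200))

    def test_untestable_profiles(self):
        assert enrichment_test(DepthProfile("F", 0, 0, 100, 200)).verdict == "untestable"
        assert enrichment_test(DepthProfile("F", 5, 0, 100, 0)).verdict == "untestable"

    def test_p_value_monotone_in_in_count(self):
        ps = [enrichment_test(DepthProfile("F", k, 20 - k, 100, 200)).p_value
              for k in range(21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_bh_qvalues_match_reference_stepup():
    rng = np.random.default_rng(41)
    feats = [feat(1000 + i * 1000, 1060 + i * 1000, name=f"F{i}") for i in range(40)]
    mids = []
    for i in range(40):
        n = int(rng.integers(6, 30))
        mids.extend(rng.integers(1000 + i * 1000 - 60, 1120 + i * 1000, n))
    report = validate_features(
        feats, {("chr1", "+"): sorted(int(m) for m in mids)},
        {"chr1": 100000}, all_features=feats)
    expected = bh_stepup(list(report["p"]))
    assert np.allclose(report["q"], expected)


def test_verdict_requires_all_three_gates():
    feats = [feat(1000, 1060, name="lowreads"), feat(5000, 5060, name="strong")]
    mids = sorted(
        [1010, 1020, 1030]              # 3 reads inside: below min_reads
        + [5000 + 10 * k for k in range(6)]  # 60 reads inside "strong"
        * 10
    )
    report = validate_features(
        feats, {("chr1", "+"): mids}, {"chr1": 100000},
        min_reads=5, all_features=feats).set_index("feature")
    assert report.loc["strong", "verdict"] == "valid"
    assert report.loc["lowreads", "verdict"] == "invalid"


def test_curate_drops_invalid_rows_only(tmp_path):
    reads = (
        [asg(f"r{i}", (1, 1), f"AAAA{i:02d}", "good") for i in range(5)]
        + [asg(f"s{i}", (1, 1), f"CCCC{i:02d}", "bad") for i in range(10)]
    )
    matrix = dedup_and_count(reads, PIXELS)
    import pandas as pd

    results = pd.DataFrame(
        {"feature": ["good", "bad", "odd"],
         "verdict": ["valid", "invalid", "untestable"]}
    )
    curated = curate(matrix, results)
    assert curated.feature_names == ["good"]
    assert curated.total() == matrix.total() - 10  # conservation
    # empty results: unchanged with a warning
    assert curate(matrix, results.iloc[0:0]).equals(matrix)


def test_non_small_rna_classes_skipped_by_default():
    feats = [feat(1000, 1060, name="M", cls="mRNA"),
             feat(3000, 3060, name="S", cls="miRNA")]
    report = validate_features(feats, {("chr1", "+"): [3010] * 30},
                               {"chr1": 100000}, all_features=feats)
    assert list(report["feature"]) == ["S"]
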