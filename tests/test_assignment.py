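"""Overlap-score assignment: exact arithmetic, tie naming, strand policy,
and equivalence with the exhaustive scorer."""

from fractions import Fraction

import numpy as np
import pytest

from spotrna.annotation import AnnotationIndex, Feature
from spotrna.assignment import (
    AlignedFragment,
    assign_read,
    decode_read_name,
    encode_read_name,
    overlap_score,
)
from spotrna.barcode_calling import PixelID

from _oracles import assign_oracle


def frag(blocks, strand="+", chrom="chr1"):
    return AlignedFragment("r1", chrom, strand, tuple(blocks))


def exon(name, start, end, strand="+", cls="mRNA"):
    return Feature(name, cls, "chr1", start, end, strand, "exon", parent=f"{name}.t")


def intron(name, start, end, strand="+"):
    return Feature(name, "mRNA", "chr1", start, end, strand, "intron", parent=f"{name}.t")


class TestOverlapScore:
    def test_contained_fragment(self):
        assert overlap_score(frag([(150, 250)]), exon("A", 0, 1000)) == Fraction(1, 10)

    def test_partial_overlap_negative(self):
        assert overlap_score(frag([(140, 240)]), exon("A", 200, 400)) == Fraction(-1, 10)

    def test_spliced_blocks_summed(self):
        f = frag([(10, 30), (70, 90)])
        assert overlap_score(f, exon("A", 0, 100)) == Fraction(2, 5)

    def test_upper_bound_reached_iff_contained(self):
        feature = exon("A", 100, 500)
        inside = frag([(150, 210)])
        straddle = frag([(80, 140)])
        assert overlap_score(inside, feature) == Fraction(60, 400)
        assert overlap_score(straddle, feature) < Fraction(60, 400)

    def test_monotone_in_overlap(self):
        # moving one aligned base into the feature raises the score by 2/L_a
        feature = exon("A", 100, 500)
        s1 = overlap_score(frag([(60, 120)]), feature)
        s2 = overlap_score(frag([(61, 121)]), feature)
        assert s2 - s1 == Fraction(2, 400)


class TestAssignRead:
    def test_sole_exon_candidate(self):
        idx = AnnotationIndex([exon("A", 100, 300)])
        a = assign_read(frag([(150, 210)]), idx)
        assert (a.feature_name, a.layer, a.status) == ("A", "exon", "assigned")

    def test_shorter_feature_wins(self):
        idx = AnnotationIndex([exon("A", 0, 1000), exon("B", 100, 600)])
        a = assign_read(frag([(200, 300)]), idx)
        assert a.feature_name == "B"
        assert a.score == Fraction(1, 5)

    def test_equal_length_tie_plus_named(self):
        idx = AnnotationIndex([exon("B", 100, 600), exon("A", 100, 600)])
        a = assign_read(frag([(200, 300)]), idx)
        assert a.feature_name == "A+B"  # sorted, plus-joined
        assert a.layer == "exon"

    def test_sole_intron_candidate(self):
        idx = AnnotationIndex([intron("A", 1000, 1400), exon("A", 400, 1000)])
        a = assign_read(frag([(1100, 1200)]), idx)
        assert (a.feature_name, a.layer) == ("A", "intron")

    def test_no_positive_candidate_unassigned(self):
        idx = AnnotationIndex([exon("A", 200, 400)])
        # 40 bases in, 60 out -> score < 0
        a = assign_read(frag([(140, 240)]), idx)
        assert a.status == "unassigned"

    def test_exon_wins_exon_intron_tie(self):
        # overlapping genes: an exon of A and an intron of B share the span
        idx = AnnotationIndex([exon("A", 100, 300), intron("B", 100, 300)])
        a = assign_read(frag([(150, 250)]), idx)
        assert a.layer == "exon"
        assert a.feature_name == "A+B"

    def test_spliced_fragment_skips_gap_features(self):
        # intron spans the splice gap but no aligned block -> not a candidate
        idx = AnnotationIndex([exon("A", 0, 100), exon("A", 200, 300),
                               intron("A", 100, 200)])
        a = assign_read(frag([(64, 100), (200, 224)]), idx)
        assert (a.feature_name, a.layer) == ("A", "exon")

    def test_strand_policy(self):
        idx = AnnotationIndex([exon("P", 100, 300, "+"), exon("M", 100, 300, "-")])
        plus = frag([(150, 250)], "+")
        minus = frag([(150, 250)], "-")
        assert assign_read(plus, idx, "same").feature_name == "P"
        assert assign_read(minus, idx, "same").feature_name == "M"
        assert assign_read(plus, idx, "opposite").feature_name == "M"
        assert assign_read(plus, idx, "both").feature_name == "M+P"
        with pytest.raises(ValueError):
            assign_read(plus, idx, "either")


def random_features(rng, n):
    feats = []
    for i in range(n):
        s = int(rng.integers(0, 3000))
        length = int(rng.integers(20, 600))
        feats.append(
            Feature(f"F{i}", "mRNA", "chr1", s, s + length,
                    "+-"[rng.integers(0, 2)],
                    ["exon", "intron"][rng.integers(0, 2)], parent="p")
        )
    return feats


def random_fragment(rng):
    s = int(rng.integers(0, 3200))
    if rng.random() < 0.3:  # spliced
        l1, gap, l2 = (int(rng.integers(10, 60)), int(rng.integers(30, 300)),
                       int(rng.integers(10, 60)))
        blocks = ((s, s + l1), (s + l1 + gap, s + l1 + gap + l2))
    else:
        blocks = ((s, s + int(rng.integers(15, 120))),)
    return frag(blocks, "+-"[rng.integers(0, 2)])


def test_winner_and_tie_set_match_exhaustive_scorer():
    rng = np.random.default_rng(21)
    n_checked = 0
    for _ in range(60):
        feats = random_features(rng, int(rng.integers(2, 51)))
        idx = AnnotationIndex(feats)
        for _ in range(25):
            f = random_fragment(rng)
            got = assign_read(f, idx)
            expect = assign_oracle(f, feats)
            if expect is None:
                assert got.status == "unassigned"
            else:
                assert got.status == "assigned"
                assert (got.feature_name, got.layer, got.score) == expect
                n_checked += 1
    assert n_checked > 100


def test_read_name_metadata_round_trip():
    name = encode_read_name("read7", PixelID(3, 17), "ACGTAC")
    assert name == "read7|PX:3x17|UMI:ACGTAC"
    orig, pixel, umi = decode_read_name(name)
    assert (orig, pixel, umi) == ("read7", PixelID(3, 17), "ACGTAC")
    assert decode_read_name("plain") == ("plain", None, "")
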