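"""Annotation ingestion, merging, intron derivation and interval index."""

import numpy as np
import pytest

from spotrna.annotation import (
    AnnotationError,
    AnnotationIndex,
    Feature,
    derive_introns,
    load_sources,
    merge_similar,
    read_merged_gtf,
    write_merged_gtf,
)


def write(path, text):
    path.write_text(text)
    return str(path)


def test_gtf_coordinates_converted_to_zero_based_half_open(tmp_path):
    gtf = write(
        tmp_path / "a.gtf",
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G"; gene_name "G"; '
        'gene_type "protein_coding"; transcript_id "G.t1";\n',
    )
    (feat,) = load_sources([(gtf, "gencode")])
    assert (feat.start, feat.end) == (100, 200)
    assert feat.rna_class == "mRNA" and feat.record_kind == "exon"


def test_mirna_hairpin_and_mature_arms(tmp_path):
    gtf = write(
        tmp_path / "mir.gtf",
        "\n".join(
            [
                'chr1\tsrc\tmiRNA_primary_transcript\t1001\t1070\t.\t+\t.\tName "mir-X";',
                'chr1\tsrc\tmiRNA\t1001\t1022\t.\t+\t.\tName "miR-X-5p"; Derives_from "mir-X";',
                'chr1\tsrc\tmiRNA\t1049\t1070\t.\t+\t.\tName "miR-X-3p"; Derives_from "mir-X";',
            ]
        )
        + "\n",
    )
    feats = load_sources([(gtf, "gtf")])
    by_name = {f.name: f for f in feats}
    assert by_name["mir-X"].record_kind == "transcript"
    for arm in ("miR-X-5p", "miR-X-3p"):
        assert by_name[arm].record_kind == "exon"
        assert by_name[arm].parent == "mir-X"
        assert by_name[arm].rna_class == "miRNA"


def test_bed6_class_column(tmp_path):
    bed = write(tmp_path / "s.bed", "chr2\t50\t110\tSNORD1\t0\t-\tsnoRNA\n")
    feats = load_sources([(bed, "bed6")])
    exon = next(f for f in feats if f.record_kind == "exon")
    assert (exon.name, exon.rna_class, exon.start, exon.end, exon.strand) == (
        "SNORD1", "snoRNA", 50, 110, "-",
    )
    # every exon has a parent transcript
    assert any(f.record_kind == "transcript" and f.name == exon.parent for f in feats)


def test_empty_source_is_empty_list(tmp_path):
    gtf = write(tmp_path / "empty.gtf", "")
    assert load_sources([(gtf, "gtf")]) == []


def test_malformed_line_reports_file_and_line(tmp_path):
    gtf = write(tmp_path / "bad.gtf", "chr1\tonly\tthree\n")
    with pytest.raises(AnnotationError, match=r"bad\.gtf:1"):
        load_sources([(gtf, "gtf")])
    with pytest.raises(AnnotationError, match="dialect"):
        load_sources([(str(tmp_path / "x"), "nope")])


def mk(name, start, end, strand="+", cls="snoRNA", kind="exon", rank=0):
    return Feature(name, cls, "chr1", start, end, strand, kind,
                   parent=f"{name}.t", source_rank=rank)


class TestMergeSimilar:
    def test_identical_records_collapse_and_idempotent(self):
        feats = [mk("A", 100, 200, rank=0), mk("A2", 100, 200, rank=1)]
        merged = merge_similar(feats, 0.9)
        assert len(merged) == 1
        assert merged[0].name == "A"  # higher-priority source wins naming
        assert merge_similar(merged, 0.9) == merged  # idempotent

    def test_reciprocal_overlap_union_span(self):
        # overlap 95 bases: 95/100 and 95/102, both >= 0.9
        feats = [mk("A", 0, 100), mk("B", 5, 107, rank=1)]
        merged = merge_similar(feats, 0.9)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 107)

    def test_below_threshold_not_merged(self):
        feats = [mk("A", 0, 100), mk("B", 50, 150, rank=1)]  # 50% reciprocal
        assert len(merge_similar(feats, 0.9)) == 2

    def test_opposite_strands_never_merge(self):
        feats = [mk("A", 0, 100, "+"), mk("B", 0, 100, "-", rank=1)]
        assert len(merge_similar(feats, 0.9)) == 2

    def test_order_insensitive(self):
        feats = [mk("A", 0, 100), mk("B", 5, 107, rank=1), mk("C", 500, 600, rank=2)]
        a = merge_similar(feats, 0.9)
        b = merge_similar(list(reversed(feats)), 0.9)
        assert a == b


class TestDeriveIntrons:
    def tx(self, start, end, exon_spans):
        feats = [Feature("G.t1", "mRNA", "chr1", start, end, "+",
                         "transcript", parent="G")]
        feats += [Feature("G", "mRNA", "chr1", s, e, "+", "exon", parent="G.t1")
                  for s, e in exon_spans]
        return feats

    def test_single_gap(self):
        introns = derive_introns(self.tx(0, 300, [(0, 100), (200, 300)]))
        assert [(i.start, i.end) for i in introns] == [(100, 200)]
        assert introns[0].name == "G" and introns[0].record_kind == "intron"

    def test_single_exon_no_introns(self):
        assert derive_introns(self.tx(0, 100, [(0, 100)])) == []

    def test_abutting_exons_no_introns(self):
        assert derive_introns(self.tx(0, 200, [(0, 100), (100, 200)])) == []

    def test_exon_outside_transcript_is_error(self):
        with pytest.raises(AnnotationError, match="G.t1"):
            derive_introns(self.tx(0, 100, [(0, 150)]))

    def test_partition_property(self):
        """Exon union and intron union partition the transcript interval."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_ex = int(rng.integers(1, 6))
            bounds = np.sort(rng.choice(np.arange(1, 1000), 2 * n_ex, replace=False))
            spans = [(int(bounds[2 * i]), int(bounds[2 * i + 1]))
                     for i in range(n_ex)]
            feats = self.tx(spans[0][0], spans[-1][1], spans)
            introns = derive_introns(feats)
            covered = set()
            for f in feats[1:] + introns:
                span = set(range(f.start, f.end))
                assert not (covered & span)  # exon/intron bases disjoint
                covered |= span
            tx = feats[0]
            assert covered == set(range(tx.start, tx.end))


def test_index_matches_brute_force_scan():
    rng = np.random.default_rng(4)
    feats = []
    for i in range(500):
        s = int(rng.integers(0, 5000))
        e = s + int(rng.integers(1, 400))
        feats.append(
            Feature(f"F{i}", "mRNA", f"chr{rng.integers(1, 3)}", s, e,
                    "+-"[rng.integers(0, 2)],
                    ["exon", "intron", "transcript"][rng.integers(0, 3)],
                    parent="p")
        )
    index = AnnotationIndex(feats)
    for _ in range(200):
        chrom = f"chr{rng.integers(1, 3)}"
        strand = "+-"[rng.integers(0, 2)]
        s = int(rng.integers(0, 5200))
        e = s + int(rng.integers(1, 300))
        got = {id(f) for f in index.query(chrom, s, e, strand)}
        expect = {
            id(f)
            for f in feats
            if f.chrom == chrom and f.strand == strand
            and f.record_kind in ("exon", "intron")
            and min(e, f.end) > max(s, f.start)
        }
        assert got == expect


def test_merged_gtf_round_trip(tmp_path):
    feats = [
        Feature("G.t1", "mRNA", "chr1", 10, 500, "+", "transcript", parent="G"),
        Feature("G", "mRNA", "chr1", 10, 110, "+", "exon", parent="G.t1"),
        Feature("G", "mRNA", "chr1", 110, 500, "+", "intron", parent="G.t1"),
    ]
    write_merged_gtf(feats, tmp_path / "m.gtf", tmp_path / "m.tsv")
    back = read_merged_gtf(tmp_path / "m.gtf")
    assert [(f.name, f.start, f.end, f.record_kind, f.parent) for f in back] == [
        (f.name, f.start, f.end, f.record_kind, f.parent) for f in feats
    ]
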