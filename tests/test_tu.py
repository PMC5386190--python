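"""TU segmentation, g/a/i/n classification, UTRs and the leaderless rule."""

import numpy as np
import pytest

from primetx.model import (
    CONDITIONS,
    GeneAnnotation,
    SegmentationParams,
    Thresholds,
    Track,
    TranscriptionalUnit,
    TSSRecord,
)
from primetx.tu import (
    build_tus,
    classify_tus,
    compute_utrs,
    detect_leaderless,
    segment_tu,
)

TH = Thresholds()


def make_tss(position, strand="+", strain="s"):
    counts = np.zeros(len(CONDITIONS))
    counts[0] = 1000.0
    return TSSRecord(strain, "chr", strand, position, counts)


def coverage_track(values, strand="+"):
    return Track("s", "chr", strand, np.asarray(values, dtype=float), "coverage")


def make_tu(start, end, strand="+", tss_at_five_prime=True, tss_pos=None):
    if tss_pos is None:
        tss_pos = start if strand == "+" else end - 1
    return TranscriptionalUnit("tu", "s", "chr", strand, start, end,
                               make_tss(tss_pos, strand))


class TestSegmentation:
    def test_plateau_then_zero(self):
        v = np.concatenate([np.full(500, 100.0), np.zeros(300)])
        start, end, flags = segment_tu(make_tss(0), coverage_track(v))
        assert (start, end) == (0, 500)
        assert flags == ()

    def test_sustained_five_percent_ends_at_drop(self):
        """With a 10% running-max rule, coverage falling to 5% terminates."""
        v = np.concatenate([np.full(200, 100.0), np.full(400, 5.0)])
        params = SegmentationParams(min_coverage_fraction=0.1, max_gap=50)
        start, end, _ = segment_tu(make_tss(0), coverage_track(v), params)
        assert (start, end) == (0, 200)

    def test_zero_coverage_tss_is_flagged_single_nt(self):
        v = np.zeros(100)
        start, end, flags = segment_tu(make_tss(10), coverage_track(v))
        assert (start, end) == (10, 11)
        assert "zero_coverage" in flags

    def test_minus_strand_extends_leftwards(self):
        v = np.concatenate([np.zeros(100), np.full(300, 50.0), np.zeros(100)])
        start, end, _ = segment_tu(make_tss(399, "-"), coverage_track(v, "-"))
        assert (start, end) == (100, 400)

    def test_max_tu_length_respected(self):
        v = np.full(5000, 10.0)
        params = SegmentationParams(max_tu_length=1000)
        start, end, _ = segment_tu(make_tss(0), coverage_track(v), params)
        assert end - start <= 1001


GENE = GeneAnnotation("gene1", "chr", 1000, 1600, "+")


def classify_single(tu, genes, others=()):
    tus = [tu, *others]
    classify_tus(tus, genes, TH)
    return tu


class TestClassification:
    @pytest.mark.parametrize("overlap,expect_a", [(19, False), (20, True), (197, True)])
    def test_antisense_overlap_boundary(self, overlap, expect_a):
        tu = make_tu(1600 - overlap, 1900, strand="-")
        classify_single(tu, [GENE])
        assert ("a" in tu.labels) is expect_a

    def test_gene_covering_tu_is_gtu(self):
        tu = make_tu(950, 1700)
        classify_single(tu, [GENE])
        assert tu.labels == ("g",)
        assert [g.gene_id for g in tu.member_genes] == ["gene1"]

    def test_partial_sense_overlap_counts_as_g(self):
        tu = make_tu(900, 1100)
        classify_single(tu, [GENE])
        assert "g" in tu.labels

    def test_tss_strictly_inside_gene_is_itu(self):
        tu = make_tu(1200, 1400, tss_pos=1200)
        classify_single(tu, [GENE])
        assert tu.labels == ("i",)

    def test_tss_at_gene_start_is_not_internal(self):
        tu = make_tu(1000, 1700, tss_pos=1000)
        classify_single(tu, [GENE])
        assert "i" not in tu.labels
        assert "g" in tu.labels

    def test_tss_at_gene_last_position_is_not_internal(self):
        tu = make_tu(1599, 1900, tss_pos=1599)
        classify_single(tu, [GENE])
        assert "i" not in tu.labels

    def test_freestanding_is_ntu(self):
        tu = make_tu(5000, 5300)
        classify_single(tu, [GENE])
        assert tu.labels == ("n",)

    def test_antisense_to_other_tu_without_gene(self):
        tu = make_tu(5000, 5300, strand="+")
        other = make_tu(5100, 5400, strand="-")
        classify_tus([tu, other], [], TH)
        assert tu.labels == ("a",)
        assert other.labels == ("a",)

    def test_gaitu_composite(self):
        """A TU starting inside one gene, covering a downstream gene and
        running antisense to a third is a gaiTU."""
        host = GeneAnnotation("host", "chr", 1000, 1600, "+")
        downstream = GeneAnnotation("down", "chr", 1700, 2000, "+")
        anti = GeneAnnotation("anti", "chr", 2050, 2400, "-")
        tu = make_tu(1300, 2150, tss_pos=1300)
        classify_single(tu, [host, downstream, anti])
        assert tu.labels == ("g", "a", "i")
        assert tu.label_str == "gaiTU"

    def test_antisense_relation_symmetric(self):
        rng = np.random.default_rng(4)
        tus = []
        for i in range(30):
            start = int(rng.integers(0, 5000))
            length = int(rng.integers(30, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            tus.append(make_tu(start, start + length, strand=strand))
        for x in tus:
            for y in tus:
                if x.strand != y.strand:
                    assert x.overlap(y.start, y.end) == y.overlap(x.start, x.end)


class TestUTRs:
    def test_utr5_of_54(self):
        tu = make_tu(946, 1800)
        classify_single(tu, [GENE])
        compute_utrs(tu)
        assert tu.utr5_len == 54
        assert tu.utr3_len == 200

    def test_tss_at_start_codon_gives_zero_utr5(self):
        tu = make_tu(1000, 1700, tss_pos=1000)
        classify_single(tu, [GENE])
        compute_utrs(tu)
        assert tu.utr5_len == 0

    def test_tu_ending_at_stop_gives_zero_utr3(self):
        tu = make_tu(950, 1600)
        classify_single(tu, [GENE])
        compute_utrs(tu)
        assert tu.utr3_len == 0

    def test_minus_strand_utrs(self):
        gene = GeneAnnotation("g", "chr", 1000, 1600, "-")
        tu = make_tu(900, 1654, strand="-")
        classify_single(tu, [gene])
        compute_utrs(tu)
        assert tu.utr5_len == 54
        assert tu.utr3_len == 100

    def test_additivity_for_single_gene_gtu(self):
        tu = make_tu(946, 1800)
        classify_single(tu, [GENE])
        compute_utrs(tu)
        assert tu.utr5_len + len(GENE) + tu.utr3_len == len(tu)


class TestLeaderless:
    @pytest.mark.parametrize("offset,expected", [(0, True), (5, True), (10, True),
                                                 (11, False)])
    def test_upstream_window_boundary(self, offset, expected):
        gene = GeneAnnotation("g", "chr", 1000, 1600, "+")
        tss = make_tss(1000 - offset)
        tss.classes = ("gTSS",)
        flagged = detect_leaderless([tss], [gene], TH)
        assert (gene in flagged) is expected

    @pytest.mark.parametrize("offset,expected", [(0, True), (10, True), (11, False)])
    def test_minus_strand_window(self, offset, expected):
        gene = GeneAnnotation("g", "chr", 1000, 1600, "-")
        tss = make_tss(1599 + offset, "-")
        tss.classes = ("gTSS",)
        flagged = detect_leaderless([tss], [gene], TH)
        assert (gene in flagged) is expected

    def test_non_gtss_never_flags(self):
        gene = GeneAnnotation("g", "chr", 1000, 1600, "+")
        tss = make_tss(1000)
        tss.classes = ("iTSS",)
        assert detect_leaderless([tss], [gene], TH) == []


def test_build_tus_ids_deterministic(sim_default):
    tus = sim_default["results"]["A"].tus
    assert [tu.tu_id for tu in tus] == sorted([tu.tu_id for tu in tus])
    assert all(tu.labels for tu in tus)
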