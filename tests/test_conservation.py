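"""Cross-strain conservation rules and promoter-divergence scanning."""

import numpy as np
import pytest

from primetx.alignment import align_proteins
from primetx.conservation import (
    ConservationRecord,
    OrthologPair,
    conserved_gtss,
    conserved_internal_antisense_tss,
    conserved_ntss,
    map_position_via_protein,
    promoter_divergence,
)
from primetx.model import (
    CONDITIONS,
    GeneAnnotation,
    GenomeSequence,
    Thresholds,
    TranscriptionalUnit,
    TSSRecord,
)

TH = Thresholds()


def make_tss(position, strand="+", strain="A", classes=()):
    counts = np.zeros(len(CONDITIONS))
    counts[0] = 1000.0
    t = TSSRecord(strain, f"chr{strain}", strand, position, counts)
    t.classes = tuple(classes)
    return t


def make_tu(tu_id, start, end, strand="+", strain="A", labels=("n",), genes=()):
    tu = TranscriptionalUnit(tu_id, strain, f"chr{strain}", strand, start, end,
                             make_tss(start if strand == "+" else end - 1,
                                      strand, strain))
    tu.labels = tuple(labels)
    tu.member_genes = list(genes)
    return tu


def identity_pair(n_codons=60, start_a=100, start_b=300, strand_a="+",
                  strand_b="+"):
    protein = "M" + "AKLWERT"[0:6] * 10  # arbitrary repeated protein
    protein = protein[:n_codons]
    gene_a = GeneAnnotation("ga", "chrA", start_a, start_a + 3 * n_codons, strand_a)
    gene_b = GeneAnnotation("gb", "chrB", start_b, start_b + 3 * n_codons, strand_b)
    return OrthologPair(gene_a, gene_b, align_proteins(protein, protein))


class TestPositionMapping:
    def test_identity_map(self):
        pair = identity_pair()
        pos_b, exact = map_position_via_protein(pair, pair.gene_a.start + 30)
        assert exact
        assert pos_b == pair.gene_b.start + 30

    def test_one_codon_insertion_shifts_by_three(self):
        prot_a = "MWKLVRTEAG"
        prot_b = "MWKLDVRTEAG"  # one inserted residue after position 3
        gene_a = GeneAnnotation("ga", "chrA", 100, 100 + 30, "+")
        gene_b = GeneAnnotation("gb", "chrB", 500, 500 + 33, "+")
        pair = OrthologPair(gene_a, gene_b, align_proteins(prot_a, prot_b))
        # codon 6 of a ('R') aligns to codon 7 of b
        pos_b, exact = map_position_via_protein(pair, 100 + 6 * 3 + 1)
        assert exact
        assert pos_b == 500 + 7 * 3 + 1

    def test_round_trip_on_gap_free_columns(self):
        pair = identity_pair()
        reverse = OrthologPair(pair.gene_b, pair.gene_a,
                               align_proteins(pair.alignment.seq_b,
                                              pair.alignment.seq_a))
        for offset in (0, 7, 50, 100):
            pos = pair.gene_a.start + offset
            pos_b, _ = map_position_via_protein(pair, pos)
            back, _ = map_position_via_protein(reverse, pos_b)
            assert back == pos

    def test_minus_strand_gene_mapping(self):
        pair = identity_pair(strand_b="-")
        # offset 30 on the coding strand of a maps to the same coding offset
        pos_b, _ = map_position_via_protein(pair, pair.gene_a.start + 30)
        assert pos_b == (pair.gene_b.end - 1) - 30

    def test_position_outside_gene_rejected(self):
        pair = identity_pair()
        with pytest.raises(ValueError, match="outside"):
            map_position_via_protein(pair, 5)


class TestGTSSConservation:
    def _tus(self, strain, gene, with_gtss=True):
        if not with_gtss:
            return []
        return [make_tu(f"{strain}_tu", gene.start, gene.end + 50,
                        strain=strain, labels=("g",), genes=[gene])]

    def test_co_presence_is_conserved(self):
        ga = GeneAnnotation("ga", "chrA", 100, 400, "+")
        gb = GeneAnnotation("gb", "chrB", 100, 400, "+")
        records = conserved_gtss(self._tus("A", ga), self._tus("B", gb),
                                 [("ga", "gb")])
        assert [r.verdict for r in records] == ["conserved"]

    def test_one_sided_gtss_is_strain_specific(self):
        ga = GeneAnnotation("ga", "chrA", 100, 400, "+")
        gb = GeneAnnotation("gb", "chrB", 100, 400, "+")
        records = conserved_gtss(self._tus("A", ga), [], [("ga", "gb")])
        assert [r.verdict for r in records] == ["strain_specific_a"]
        records = conserved_gtss([], self._tus("B", gb), [("ga", "gb")])
        assert [r.verdict for r in records] == ["strain_specific_b"]

    def test_no_gtss_on_either_side_no_record(self):
        assert conserved_gtss([], [], [("ga", "gb")]) == []

    def test_swapped_strains_mirror_verdicts(self):
        ga = GeneAnnotation("ga", "chrA", 100, 400, "+")
        gb = GeneAnnotation("gb", "chrB", 100, 400, "+")
        fwd = conserved_gtss(self._tus("A", ga), [], [("ga", "gb")])
        rev = conserved_gtss([], self._tus("A", ga), [("gb", "ga")])
        assert fwd[0].verdict == "strain_specific_a"
        assert rev[0].verdict == "strain_specific_b"


class TestOffsetRule:
    @pytest.mark.parametrize("offset,expected", [(0, "conserved"), (10, "conserved"),
                                                 (11, "strain_specific_a")])
    def test_itss_offset_boundary(self, offset, expected):
        pair = identity_pair()
        tss_a = [make_tss(pair.gene_a.start + 60, "+", "A", ("iTSS",))]
        tss_b = [make_tss(pair.gene_b.start + 60 + offset, "+", "B", ("iTSS",))]
        records = conserved_internal_antisense_tss(tss_a, tss_b, [pair], "iTSS", TH)
        verdicts = [r.verdict for r in records]
        assert expected in verdicts
        if expected == "conserved":
            rec = records[0]
            assert rec.evidence["offset_nt"] == offset

    def test_atss_requires_antisense_strand(self):
        pair = identity_pair()
        tss_a = [make_tss(pair.gene_a.start + 60, "-", "A", ("aTSS",))]
        tss_b = [make_tss(pair.gene_b.start + 63, "-", "B", ("aTSS",))]
        records = conserved_internal_antisense_tss(tss_a, tss_b, [pair], "aTSS", TH)
        assert records[0].verdict == "conserved"
        assert records[0].evidence["offset_nt"] == 3

    def test_each_tss_matched_at_most_once(self):
        pair = identity_pair()
        tss_a = [make_tss(pair.gene_a.start + 60, "+", "A", ("iTSS",)),
                 make_tss(pair.gene_a.start + 63, "+", "A", ("iTSS",))]
        tss_b = [make_tss(pair.gene_b.start + 61, "+", "B", ("iTSS",))]
        records = conserved_internal_antisense_tss(tss_a, tss_b, [pair], "iTSS", TH)
        conserved = [r for r in records if r.verdict == "conserved"]
        assert len(conserved) == 1

    def test_unmatched_partner_reported_strain_specific_b(self):
        pair = identity_pair()
        tss_b = [make_tss(pair.gene_b.start + 60, "+", "B", ("iTSS",))]
        records = conserved_internal_antisense_tss([], tss_b, [pair], "iTSS", TH)
        assert [r.verdict for r in records] == ["strain_specific_b"]


def random_genome(rng, n, strain="A"):
    residues = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    return GenomeSequence(strain, f"chr{strain}", residues), residues


class TestNTSSConservation:
    def test_identical_ntu_conserved_as_ntu(self):
        rng = np.random.default_rng(41)
        genome_a, seq = random_genome(rng, 5000, "A")
        genome_b = GenomeSequence("B", "chrB", seq)
        ntu = make_tu("nA", 1000, 1200, strain="A", labels=("n",))
        partner = make_tu("nB", 1000, 1200, strain="B", labels=("n",))
        records = conserved_ntss([ntu], genome_a, genome_b, [partner], TH)
        assert records[0].verdict == "conserved"

    def test_low_query_coverage_not_conserved(self):
        rng = np.random.default_rng(42)
        genome_a, seq_a = random_genome(rng, 5000, "A")
        # partner genome shares only 80 of the 200 transcript nucleotides
        _, other = random_genome(rng, 5000, "B")
        seq_b = other[:2000] + seq_a[1000:1080] + other[2080:]
        genome_b = GenomeSequence("B", "chrB", seq_b)
        ntu = make_tu("nA", 1000, 1200, strain="A", labels=("n",))
        records = conserved_ntss([ntu], genome_a, genome_b, [], TH)
        assert records[0].verdict == "strain_specific_a"
        assert records[0].evidence["qcov"] < 0.5

    def test_hit_under_gtu_is_classified_differently(self):
        rng = np.random.default_rng(43)
        genome_a, seq = random_genome(rng, 5000, "A")
        genome_b = GenomeSequence("B", "chrB", seq)
        ntu = make_tu("nA", 1000, 1200, strain="A", labels=("n",))
        partner_gtu = make_tu("gB", 900, 1400, strain="B", labels=("g",))
        records = conserved_ntss([ntu], genome_a, genome_b, [partner_gtu], TH)
        assert records[0].verdict == "conserved_classified_differently"


def plant_window(seq_list, tss_pos, hexamer="TATAAT"):
    seq_list[tss_pos - 12: tss_pos - 6] = list(hexamer)
    return seq_list


class TestPromoterDivergence:
    def _genomes(self, mutant_hexamer):
        rng = np.random.default_rng(44)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 4000)))
        tss_pos = 2000
        plant_window(seq, tss_pos)
        genome_a = GenomeSequence("A", "chrA", "".join(seq))
        seq_b = list(seq)
        plant_window(seq_b, tss_pos, mutant_hexamer)
        genome_b = GenomeSequence("B", "chrB", "".join(seq_b))
        return genome_a, genome_b, make_tss(tss_pos, "+", "A", ("gTSS",))

    @pytest.mark.parametrize("mutant", ["TGTAAT", "TATGAT"])
    def test_single_minus10_transition_flagged(self, mutant):
        genome_a, genome_b, tss = self._genomes(mutant)
        report = promoter_divergence(tss, genome_a, genome_b)
        assert report.verdict == "ok"
        assert report.minus10_a == "TATAAT"
        assert report.minus10_b == mutant
        assert report.minus10_mismatch
        assert len(report.mismatches) == 1

    def test_identical_windows_report_no_mismatch(self):
        genome_a, genome_b, tss = self._genomes("TATAAT")
        report = promoter_divergence(tss, genome_a, genome_b)
        assert report.verdict == "ok"
        assert report.mismatches == []
        assert not report.minus10_mismatch

    def test_mismatch_outside_hexamer_not_flagged(self):
        genome_a, genome_b, tss = self._genomes("TATAAT")
        seq = list(genome_b.residues)
        pos = tss.position - 30
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        genome_b = GenomeSequence("B", "chrB", "".join(seq))
        report = promoter_divergence(tss, genome_a, genome_b)
        assert len(report.mismatches) == 1
        assert not report.minus10_mismatch

    def test_unalignable_locus_reported(self):
        rng = np.random.default_rng(45)
        genome_a, _ = random_genome(rng, 4000, "A")
        genome_b, _ = random_genome(rng, 4000, "B")
        tss = make_tss(2000, "+", "A", ("gTSS",))
        report = promoter_divergence(tss, genome_a, genome_b)
        assert report.verdict == "unalignable"

    def test_minus_strand_window(self):
        rng = np.random.default_rng(46)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 4000)))
        tss_pos = 2000
        # -10 element on the minus strand lies at tss+7..tss+12 (revcomp)
        seq[tss_pos + 7: tss_pos + 13] = list("ATTATA")
        genome_a = GenomeSequence("A", "chrA", "".join(seq))
        seq_b = list(seq)
        seq_b[tss_pos + 11] = "C"  # transcript-level A->G at hexamer offset 1
        genome_b = GenomeSequence("B", "chrB", "".join(seq_b))
        tss = make_tss(tss_pos, "-", "A", ("gTSS",))
        report = promoter_divergence(tss, genome_a, genome_b)
        assert report.minus10_a == "TATAAT"
        assert report.minus10_b == "TGTAAT"
        assert report.minus10_mismatch


class TestPlantedConservationRecovery:
    def test_conserved_counts_match_ground_truth(self, sim_default, compare_default):
        truth = sim_default["truth"]
        comp = compare_default
        assert comp.summary["conserved_gtss"] == len(truth.conserved_pairs("gTSS"))
        assert comp.summary["conserved_atss"] == len(truth.conserved_pairs("aTSS"))
        assert comp.summary["conserved_itss"] == len(truth.conserved_pairs("iTSS"))

    def test_conserved_verdicts_have_consistent_evidence(self, compare_default):
        for rec in compare_default.atss_records + compare_default.itss_records:
            if rec.verdict == "conserved":
                assert rec.evidence["offset_nt"] <= TH.ortholog_tss_offset_max
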