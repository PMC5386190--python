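"""Properties of the synthetic two-strain generator."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from primetx.model import Thresholds
from primetx.simulate import (
    SimConfig,
    generate_genome_pair,
    simulate_read_starts,
    write_fixture,
)

from conftest import small_config


class TestLayout:
    def test_default_ortholog_table_has_120_pairs(self, sim_default):
        assert len(sim_default["ortholog_ids"]) == 120

    def test_no_strain_specific_genes_equal_counts(self):
        cfg = small_config(seed=6, n_strain_specific_genes=0)
        _, genes, _, _ = generate_genome_pair(cfg)
        assert len(genes["A"]) == len(genes["B"])

    def test_infeasible_packing_rejected_before_emission(self):
        cfg = small_config(seed=6, genome_length=10_000)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome_pair(cfg)

    def test_planted_tss_counts_match_config(self, sim_default):
        truth = sim_default["truth"]
        cfg = sim_default["config"]
        for strain in "AB":
            by_class = {}
            for t in truth.tss_for(strain):
                by_class[t.tss_class] = by_class.get(t.tss_class, 0) + 1
            assert by_class["aTSS"] == cfg.n_atss
            assert by_class["iTSS"] == cfg.n_itss
            # free-standing: planted nTSS plus no-readthrough decoy sRNAs
            assert by_class["nTSS"] >= cfg.n_ntss

    def test_leaderless_genes_within_window(self, sim_default):
        truth = sim_default["truth"]
        genes = {g.gene_id: g for g in sim_default["genes"]["A"]}
        tss_by_gene = {t.gene_id: t for t in truth.tss_for("A")
                       if t.tss_class == "gTSS"}
        assert len(truth.leaderless["A"]) == sim_default["config"].n_leaderless
        for gid in truth.leaderless["A"]:
            gene, tss = genes[gid], tss_by_gene[gid]
            offset = (gene.start - tss.position if gene.strand == "+"
                      else tss.position - (gene.end - 1))
            assert 0 <= offset <= 10


class TestDeterminism:
    def test_same_seed_gives_byte_identical_fixture(self, tmp_path):
        cfg = small_config(seed=9)
        d1, d2 = tmp_path / "f1", tmp_path / "f2"
        write_fixture(cfg, d1)
        write_fixture(small_config(seed=9), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_seed_change_same_census_different_content(self, tmp_path):
        d1, d2 = tmp_path / "f1", tmp_path / "f2"
        write_fixture(small_config(seed=9), d1)
        write_fixture(small_config(seed=10), d2)
        census1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        census2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert census1 == census2
        assert (d1 / "A.fasta").read_bytes() != (d2 / "A.fasta").read_bytes()

    def test_track_file_census(self, tmp_path):
        d = tmp_path / "f"
        write_fixture(small_config(seed=9), d)
        tracks = list((d / "tracks").glob("*.bedgraph"))
        # 2 strains x 11 libraries x 2 semantics x 2 strands
        assert len(tracks) == 88
        for name in ("A.fasta", "B.fasta", "A.gff3", "B.gff3",
                     "orthologs.tsv", "config.yaml", "libraries.tsv"):
            assert (d / name).exists()


class TestExpressionModel:
    def test_zero_dispersion_zero_background_counts_equal_means(self):
        cfg = small_config(seed=8, nb_dispersion=0.0, background_per_kb=0.0)
        _, _, _, truth = generate_genome_pair(cfg)
        libs = simulate_read_starts(truth, cfg)
        planted = truth.tss_for("A")
        for ci, lib in enumerate(libs["A"][:10]):
            for t in planted:
                expected = t.baseline * t.multipliers[ci]
                got = lib.track("read_starts", t.strand).values[t.position]
                assert got == pytest.approx(expected), (ci, t.position)

    def test_readthrough_fraction_recovered_in_expectation(self):
        """Mean downstream-gene coverage = planted fraction x sRNA coverage,
        averaged over >=200 simulated condition draws."""
        cfg = small_config(seed=8, readthrough_range=(0.2, 0.2))
        _, genes, _, truth = generate_genome_pair(cfg)
        act = next(a for a in truth.actuatons if a.strain == "A" and a.decoy is None)
        gene = next(g for g in genes["A"] if g.gene_id == act.downstream_gene)
        ratios = []
        for rep in range(20):  # 20 seeds x 10 conditions = 200 draws
            cfg_rep = small_config(seed=100 + rep, readthrough_range=(0.2, 0.2))
            libs = simulate_read_starts(truth, cfg_rep)
            for lib in libs["A"][:10]:
                cov = lib.track("coverage", act.strand).values
                # compare against the sRNA body beyond the 5'-enriched peak
                if act.strand == "+":
                    srna = cov[act.srna_start + 50: act.srna_end].mean()
                else:
                    srna = cov[act.srna_start: act.srna_end - 50].mean()
                body = cov[gene.start: gene.end].mean()
                if srna > 0:
                    ratios.append(body / srna)
        assert np.mean(ratios) == pytest.approx(0.2, rel=0.1)

    def test_planted_uef_recovered_noise_free(self, sim_noisefree):
        """The UEF of a recovered TSS matches the planted multiplier ratio."""
        truth = sim_noisefree["truth"]
        result = sim_noisefree["results"]["A"]
        by_key = {(t.strand, t.tss.position): t for t in result.tus}
        checked = 0
        for t in truth.tss_for("A"):
            tu = by_key.get((t.strand, t.position))
            if tu is None:
                continue
            m = sorted(t.multipliers, reverse=True)
            expected = m[0] / m[1]
            counts = np.asarray(tu.expression)
            top, second = sorted(counts, reverse=True)[:2]
            got = top / second
            assert got == pytest.approx(expected, rel=0.05)
            checked += 1
        assert checked > 100

    def test_background_fails_ratio_rule_in_expectation(self, sim_default):
        """Spurious start positions carry excess coverage, so their mean
        start/coverage ratio stays below the calling threshold."""
        lib = sim_default["libraries"]["A"][0]
        truth_positions = {(t.strand, t.position)
                           for t in sim_default["truth"].tss_for("A")}
        starts = lib.track("read_starts", "+").values
        coverage = lib.track("coverage", "+").values
        # positions with starts but outside planted TUs are background
        planted_cover = np.zeros(len(starts), dtype=bool)
        for t in sim_default["truth"].tss_for("A"):
            if t.strand == "+":
                planted_cover[t.tu_start: t.tu_end + 150] = True
        bg = (starts > 0) & ~planted_cover
        ratios = starts[bg] / np.maximum(coverage[bg], 1e-9)
        assert np.mean(ratios) < Thresholds().min_start_coverage_ratio


class TestConservationBookkeeping:
    def test_conserved_pairs_obey_class_rules(self, sim_default):
        truth = sim_default["truth"]
        for ta, tb in truth.conserved_pairs("gTSS"):
            assert ta.gene_id and tb.gene_id
        for cls in ("aTSS", "iTSS"):
            for ta, tb in truth.conserved_pairs(cls):
                assert abs(tb.position - ta.position) <= 10
        for ta, tb in truth.conserved_pairs("nTSS"):
            # conserved free-standing transcripts share their span
            assert (ta.tu_start, ta.tu_end) == (tb.tu_start, tb.tu_end)

    def test_promoter_snp_cases_silent_in_strain_b(self, sim_default):
        truth = sim_default["truth"]
        b_positions = {(t.strand, t.position) for t in truth.tss_for("B")}
        assert len(truth.snps) == sim_default["config"].n_promoter_snp_cases
        for snp in truth.snps:
            assert snp.active_strain == "A"
            assert (snp.strand, snp.tss_position) not in b_positions
            assert snp.hexamer_active == "TATAAT"
            assert sum(x != y for x, y in zip(snp.hexamer_active,
                                              snp.hexamer_silenced)) == 1

    def test_snp_window_differs_in_exactly_one_position(self, sim_default):
        genomes = sim_default["genomes"]
        for snp in sim_default["truth"].snps:
            p = snp.tss_position
            if snp.strand == "+":
                wa = genomes["A"].residues[p - 50: p]
                wb = genomes["B"].residues[p - 50: p]
            else:
                wa = genomes["A"].residues[p + 1: p + 51]
                wb = genomes["B"].residues[p + 1: p + 51]
            assert sum(x != y for x, y in zip(wa, wb)) == 1
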