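"""Shared fixtures: synthetic datasets at default and degenerate noise.

The heavy objects (full two-strain dataset, per-strain runs, comparison)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from primetx.model import Thresholds
from primetx.pipeline import StrainInputs, run_compare, run_single
from primetx.simulate import SimConfig, generate_genome_pair, simulate_read_starts

#: seed for the default-noise dataset used throughout the suite
DEFAULT_SEED = 11
NOISEFREE_SEED = 13


@pytest.fixture(scope="session")
def sim_default():
    """Default-condition two-strain dataset plus both per-strain runs."""
    config = SimConfig(seed=DEFAULT_SEED)
    genomes, genes, ortholog_ids, truth = generate_genome_pair(config)
    libraries = simulate_read_starts(truth, config)
    results = {
        strain: run_single(StrainInputs(strain, genomes[strain], genes[strain],
                                        libraries[strain]))
        for strain in "AB"
    }
    return {
        "config": config,
        "genomes": genomes,
        "genes": genes,
        "ortholog_ids": ortholog_ids,
        "truth": truth,
        "libraries": libraries,
        "results": results,
    }


@pytest.fixture(scope="session")
def compare_default(sim_default):
    return run_compare(sim_default["results"]["A"], sim_default["results"]["B"],
                       sim_default["ortholog_ids"], seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def sim_noisefree():
    """Degenerate-noise dataset: deterministic means, no background."""
    config = SimConfig(seed=NOISEFREE_SEED, nb_dispersion=0.0,
                       background_per_kb=0.0)
    genomes, genes, ortholog_ids, truth = generate_genome_pair(config)
    libraries = simulate_read_starts(truth, config)
    results = {
        strain: run_single(StrainInputs(strain, genomes[strain], genes[strain],
                                        libraries[strain]))
        for strain in "AB"
    }
    return {
        "config": config,
        "genomes": genomes,
        "genes": genes,
        "ortholog_ids": ortholog_ids,
        "truth": truth,
        "libraries": libraries,
        "results": results,
    }


def small_config(seed: int = 5, **overrides) -> SimConfig:
    """A reduced study layout for tests that regenerate data repeatedly."""
    base = dict(
        seed=seed,
        genome_length=60_000,
        n_ortholog_genes=24,
        n_strain_specific_genes=3,
        n_gtss=20,
        n_atss=4,
        n_itss=4,
        n_ntss=6,
        n_conserved_gtss=16,
        n_conserved_atss=2,
        n_conserved_itss=2,
        n_conserved_ntss=4,
        n_promoter_snp_cases=2,
        n_actuatons=2,
        n_decoy_actuatons=2,
        n_leaderless=4,
    )
    base.update(overrides)
    return SimConfig(**base)


def recovered_tss_keys(result) -> set:
    return {(t.strand, t.position) for t in result.tss_records}


def planted_tss_keys(truth, strain: str) -> set:
    return {(t.strand, t.position) for t in truth.tss_for(strain)}
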