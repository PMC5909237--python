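"""Shared fixtures: small seeded simulation worlds.

All fixtures are generated programmatically; session scope keeps the
heavier default-parameter runs to a single execution.
"""

from __future__ import annotations

import numpy as np
import pytest

import hgtmosaic as hm


@pytest.fixture(scope="session")
def small_config() -> hm.SimConfig:
    """Desk-scale world: 200 kb, 180 genes, default noise."""
    return hm.SimConfig(genome_length=200_000, n_genes=180, rng_seed=7)


@pytest.fixture(scope="session")
def small_pair(small_config) -> hm.AncestralPair:
    return hm.generate_ancestral_pair(small_config)


@pytest.fixture(scope="session")
def small_clone(small_pair):
    truth, evidence = hm.simulate_clone(small_pair, "cloneA", n_segments=2, n_denovo=5)
    return truth, evidence


@pytest.fixture(scope="session")
def noisefree_config() -> hm.SimConfig:
    """Same world with every evidence-level error rate at zero."""
    return hm.SimConfig(
        genome_length=200_000,
        n_genes=180,
        rng_seed=7,
        map_error=0.0,
        genotype_miscall_rate=0.0,
        genotype_missing_rate=0.0,
        inconsistency_rate=0.0,
    )


@pytest.fixture(scope="session")
def noisefree_pair(noisefree_config) -> hm.AncestralPair:
    return hm.generate_ancestral_pair(noisefree_config)


@pytest.fixture(scope="session")
def noisefree_clone(noisefree_pair):
    truth, evidence = hm.simulate_clone(noisefree_pair, "cloneNF", n_segments=2, n_denovo=8)
    return truth, evidence


def run_default_seed(seed: int, n_segments: int = 2, n_denovo: int = 5):
    """One clone of the stated default world (1 Mb, 1% divergence, 100x,
    map error 0.01, miscall 0.002)."""
    cfg = hm.SimConfig(rng_seed=seed)
    pair = hm.generate_ancestral_pair(cfg)
    truth, evidence = hm.simulate_clone(pair, f"clone_s{seed}", n_segments=n_segments, n_denovo=n_denovo)
    analysis = hm.analyse_clone(pair, evidence)
    return pair, truth, evidence, analysis


@pytest.fixture(scope="session")
def default_runs():
    """Twenty seeded clones of the default world with full analyses.

    Shared by the method-agreement and breakpoint-recovery checks so the
    simulation cost is paid once.
    """
    return [run_default_seed(seed) for seed in range(1, 21)]
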