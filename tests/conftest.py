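"""Shared fixtures: the deterministic toy dataset and simulated cohorts.

The ``tiny_*`` configurations shrink every dimension of the simulation
(chromosome, deme size, divergence times) so that property tests can run
dozens of replicates in seconds; the session-scoped ``default_rep`` runs
one replicate under the generator's standard study conditions.
"""
from __future__ import annotations

import numpy as np
import pytest

from tibscan.simulate import (SimConfig, make_toy_fixture, pooled_haplotypes,
                              simulate_trio)

TINY = SimConfig(
    n_focal=15, n_out1=15, n_out2=15,
    chrom_length_bp=600_000, n_sites=400,
    mut_rate=1e-9, recomb_rate=1.5e-6,
    n_generations_burnin=20, n_generations_split1=60,
    n_generations_split2=30, sweep_start_gen=60,
    pop_size=80, sweep_pos_bp=300_000,
    sweep_init_freq=0.02, sweep_final_freq_range=(0.5, 0.95),
    max_sweep_retries=80,
)


@pytest.fixture
def toy():
    return make_toy_fixture()


@pytest.fixture
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def default_rep():
    """One replicate under the standard study conditions, with the scan run."""
    from tibscan.model import SelectionScan

    res = simulate_trio(SimConfig(seed=101))
    hm, rows = pooled_haplotypes(res)
    fit = SelectionScan(res.genotypes, hm, res.popmap).fit()
    return res, hm, rows, fit


@pytest.fixture(scope="session")
def tiny_rep():
    res = simulate_trio(TINY)
    hm, rows = pooled_haplotypes(res)
    return res, hm, rows


def random_haplotypes(n_hap, n_sites, seed, span=500_000):
    """Unstructured random phased haplotypes for oracle comparisons."""
    from tibscan.io import HaplotypeMatrix, make_variant_table

    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    pos = np.sort(rng.choice(span, n_sites, replace=False)) + 1
    vt = make_variant_table(["1"] * n_sites, pos, ["A"] * n_sites,
                            ["C"] * n_sites)
    return HaplotypeMatrix([f"h{i}" for i in range(n_hap)], vt, alleles)
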