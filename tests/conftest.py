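"""Shared fixtures: a small MAGIC simulation reused across test modules."""

import numpy as np
import pytest

import magicqtl as m


@pytest.fixture(scope="session")
def small_map():
    return m.make_map(2, [100.0, 120.0], 60, seed=11)


@pytest.fixture(scope="session")
def founders(small_map):
    return m.simulate_founder_alleles(small_map, seed=12)


@pytest.fixture(scope="session")
def population(small_map, founders):
    plan = m.make_funnel_plan(n_funnels=25, n_lines=200, seed=13)
    return m.simulate_population(small_map, founders, plan, seed=14)


@pytest.fixture(scope="session")
def prob_grid(population):
    return m.probability_grid(population, step_cM=2.0, uncertainty=0.05)


@pytest.fixture(scope="session")
def weights(population):
    return m.funnel_weights(population.funnel_ids)


def simulate_single_qtl_trait(pop, chrom, pos, pve, seed, mode="biallelic", pattern=None):
    """One trait whose only genetic variance is a planted QTL of the given PVE."""
    q = m.PlantedQTL(
        chrom, pos, mode, np.array([1.0]), np.array([1.0]), founder_pattern=pattern
    )
    arch = m.TraitArchitecture(["T1"], [q], np.array([pve]))
    ph = m.simulate_phenotypes(pop, arch, years=1, replicates=1, seed=seed)
    return ph.wide(1)["T1"].reindex(pop.line_ids).to_numpy()
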