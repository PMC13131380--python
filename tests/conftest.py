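"""Shared fixtures: small pedigrees, genomes and populations."""

import numpy as np
import pandas as pd
import pytest

from ipsim.genome import GenomeMap
from ipsim.popsim import SimConfig, TraitModel, simulate_population


def make_random_pedigree(n: int, rng: np.random.Generator, n_founders: int = 10) -> pd.DataFrame:
    """Random multi-generation pedigree with inbreeding loops.

    Animals beyond the founders draw both parents among earlier animals
    of the right sex; ids are 1..n in birth order.
    """
    sex = rng.integers(0, 2, size=n)
    sex[:2] = [0, 1]  # guarantee both sexes among founders
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == 0) + 1
        females = np.flatnonzero(sex[:i] == 1) + 1
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
    return pd.DataFrame({
        "id": np.arange(1, n + 1), "sire": sire, "dam": dam,
        "sex": np.where(sex == 0, "M", "F"), "generation": 0,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def random_pedigree_200(rng):
    return make_random_pedigree(200, rng)


def small_sim_config(**overrides) -> SimConfig:
    """A seconds-scale simulation: 5 chromosomes, few hundred animals."""
    base = dict(
        historical_schedule=((60, 30, 20), (30, 20, 20)),
        expansion_generations=4,
        n_sires=8,
        n_dams=30,
        max_dams=40,
        n_generations=6,
        litter_size=5,
        training_generations=(3, 4, 5),
        validation_generation=6,
        n_chromosomes=5,
        n_snps=600,
        n_qtl=40,
        total_cM=500.0,
        pool_multiplier=6.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_population():
    """One small simulated population reused by read-only tests."""
    cfg = small_sim_config()
    return cfg, simulate_population(cfg, TraitModel(), seed=7)


@pytest.fixture
def tiny_genome():
    return GenomeMap(
        chrom_length_cM=[100.0, 80.0],
        positions=[np.array([5.0, 30.0, 55.0, 90.0]), np.array([10.0, 40.0, 70.0])],
        is_qtl=[np.array([False, True, False, False]),
                np.array([False, False, True])],
        mutation_rate=0.0,
    )
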