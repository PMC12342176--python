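"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

from popgs.config import SimulationConfig
from popgs.simpop import simulate_population


@pytest.fixture(scope="session")
def family_pop():
    """Two-generation full-sib population: 10 families × 20 progeny, 400 markers."""
    cfg = SimulationConfig(
        n_founders=16,
        n_families=10,
        progeny_per_family=20,
        n_generations=2,
        chromosomes=[(10_000_000, 400)],
        ld_rho=0.8,
        n_qtn_per_trait=10,
        seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def two_family_pop():
    """Two clearly separated families for structure tests."""
    cfg = SimulationConfig(
        n_founders=8,
        n_families=2,
        progeny_per_family=15,
        n_generations=1,
        chromosomes=[(5_000_000, 300)],
        ld_rho=0.5,
        seed=21,
    )
    return simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
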