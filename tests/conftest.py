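import numpy as np
import pandas as pd
import pytest

from cslink.simulate import DEFAULT_FIXED_EFFECTS, SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick, modest synthetic dataset reused across read-only tests."""
    config = SimulationConfig(
        n_regions=4,
        clusters_per_region=(10, 14),
        women_per_cluster=(8, 12),
        n_facilities=30,
        n_caesarean_facilities=24,
        seed=42,
    )
    return simulate_population(config)


@pytest.fixture()
def null_effects():
    """Fixed effects all zero (intercept included)."""
    return {k: 0.0 for k in DEFAULT_FIXED_EFFECTS}


@pytest.fixture(scope="session")
def random_facilities(rng):
    """A small facility table with all indicator columns present."""
    from cslink.scores import INDICATOR_SETS

    n = 30
    local = np.random.default_rng(7)
    table = pd.DataFrame(
        {
            "facility_id": [f"F{i:03d}" for i in range(n)],
            "x": local.uniform(0, 100, n),
            "y": local.uniform(0, 100, n),
            "provides_caesarean": local.random(n) < 0.8,
        }
    )
    for cols in INDICATOR_SETS.values():
        for col in cols:
            table[col] = local.integers(0, 2, n)
    return table
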