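import numpy as np
import pandas as pd
import pytest

from metasandy.simulate import (
    SimulationConfig,
    SimulatedStudy,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study() -> SimulatedStudy:
    """A compact simulated study shared across read-only tests."""
    cfg = SimulationConfig(
        n_beaches=10, n_levels=6, n_species=25, rank=3, loading_scale=0.5, seed=11
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "OTU1": [5000, 2000, 1500],
            "OTU2": [3000, 500, 1000],
            "OTU3": [2000, 499, 500],
        },
        index=["s1", "s2", "s3"],
    )
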