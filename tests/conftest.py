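import numpy as np
import pandas as pd
import pytest

from plastox import SimConfig, permutation_null


@pytest.fixture(scope="session")
def null_profile() -> pd.Series:
    """A fixed 10,000-gene differential profile with no planted structure."""
    rng = np.random.default_rng(42)
    return pd.Series(rng.normal(0.0, 0.1, 10_000),
                     index=[f"G{i:05d}" for i in range(10_000)])


@pytest.fixture(scope="session")
def shared_null(null_profile):
    """One reusable permutation null (set size 80, 2,000 permutations)."""
    return permutation_null(null_profile, set_size=80, n=2000, seed=7)


@pytest.fixture
def base_config() -> SimConfig:
    return SimConfig(seed=0)
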