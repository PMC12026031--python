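import numpy as np
import pandas as pd
import pytest

from csfrisk.cohort import DEFAULT_PANEL, CohortConfig, generate_trajectories


@pytest.fixture
def panel():
    return DEFAULT_PANEL


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def binary_groups():
    """156 reference / 103 pathological subjects, the reference split."""
    return pd.Series([0] * 156 + [1] * 103, index=[f"S{i:04d}" for i in range(259)])


@pytest.fixture
def small_visits(binary_groups):
    """One simulated visit table at the default trajectory truth."""
    cfg = CohortConfig()
    return generate_trajectories(binary_groups, cfg, np.random.default_rng(7))
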