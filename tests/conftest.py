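import logging
import warnings

import numpy as np
import pytest

from ilistack import (
    MemberSettings,
    SimulationConfig,
    build_season_index,
    simulate_dataset,
)

# statsmodels emits convergence/frequency chatter that drowns test output
warnings.filterwarnings("ignore", module="statsmodels")
logging.getLogger("ilistack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_series():
    """Default 7-season synthetic weekly record (the study-shaped dataset)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_index(default_series):
    return build_season_index(default_series.week_starts)


@pytest.fixture(scope="session")
def small_series():
    """A 4-season record for fast harness tests."""
    return simulate_dataset(SimulationConfig(n_seasons=4, seed=3))


@pytest.fixture(scope="session")
def small_index(small_series):
    return build_season_index(small_series.week_starts)


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced Monte-Carlo and forest sizes for test-speed harness runs."""
    return MemberSettings(eb_n_samples=800, qrf_n_trees=50, eb_cv_folds=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
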