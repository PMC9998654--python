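import numpy as np
import pytest

from weddellbloom import (GridSimConfig, generate_gridded_dataset,
                          recurring_bloom_config)


@pytest.fixture(scope="session")
def study_grid():
    """The seeded study-condition grid: 10 years monthly, blooms in 4 of
    10 austral seasons, negative wind coupling at 1-month lag, moderate
    noise.  Shared across tests; nothing mutates it."""
    config = recurring_bloom_config(seed=1)
    fields, truth = generate_gridded_dataset(config)
    return config, fields, truth


@pytest.fixture(scope="session")
def quiet_grid():
    """Noiseless, gap-free, event-free 3-year grid: every de-seasoned
    anomaly must be exactly zero on it."""
    fields, truth = generate_gridded_dataset(GridSimConfig(n_years=3, seed=0))
    return fields, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
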