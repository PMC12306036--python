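import numpy as np
import pytest

import apcsmooth as m
from apcsmooth.grid import ModelFamily, build_design


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small deterministic aggregated dataset (I=5, J=8, M=5)."""
    return m.fixture_dataset(seed=1234)


@pytest.fixture(scope="session")
def gaussian_dataset(fixture_dataset):
    """The fixture's empirical log-rates as gaussian responses."""
    y = fixture_dataset.empirical_log_rates()
    return m.APCDataset(fixture_dataset.grid, y,
                        np.ones_like(y))


@pytest.fixture(scope="session")
def poisson_toy():
    """5x5 single-year Poisson grid with a mild random log-rate surface."""
    g = m.build_grid(0, 1, 5, 0, 1, 5)
    rng = np.random.default_rng(3)
    E = np.full((5, 5), 1000.0)
    eta = -3 + 0.1 * rng.normal(size=(5, 5))
    y = rng.poisson(E * np.exp(eta)).astype(float)
    return m.APCDataset(g, y, E)


@pytest.fixture(scope="session")
def small_design(fixture_dataset):
    return build_design(fixture_dataset)


@pytest.fixture(scope="session")
def poisson_family():
    return ModelFamily("poisson")
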