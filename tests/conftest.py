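import numpy as np
import pytest

import seedspec as ss


@pytest.fixture(scope="session")
def grid825():
    """The full VNIR study grid: 825 bands spanning 423.34-1022.07 nm."""
    return ss.build_wavelength_grid(423.34, 1022.07, 825)


@pytest.fixture(scope="session")
def small_grid():
    """A cheap grid for unit tests: 61 bands, 400-700 nm."""
    return ss.build_wavelength_grid(400.0, 700.0, 61)


@pytest.fixture(scope="session")
def small_easy(small_grid):
    """4 well-separated accessions x 30 seeds on the small grid."""
    truth = ss.build_archetypes(4, small_grid, preset="easy", seed=7)
    dataset = ss.simulate_dataset(truth, 30, small_grid)
    return truth, dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
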