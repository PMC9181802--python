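import numpy as np
import pytest
from hypothesis import settings

import spatialmap as sm

settings.register_profile("ci", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_paired():
    """A small paired dataset with known truth, shared across tests."""
    paired, truths = sm.simulate_paired_datasets(
        n_pixels=150, n_genes=30, n_cells=300, n_types=4, seed=11)
    return paired, truths


@pytest.fixture(scope="session")
def grid_kernel_200():
    coords = sm.make_coords(200, "grid")
    return coords, sm.kernel_from_spec(coords, ("car", 0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
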