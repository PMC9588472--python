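import numpy as np
import pytest

from ntfa.grids import make_brain_grid
from ntfa.simulate import make_scenario, simulate_dataset


@pytest.fixture(scope="session")
def small_grid():
    """Desk-scale MNI-proportioned grid (~600 in-mask voxels at 8 mm)."""
    return make_brain_grid((12, 14, 12), 8.0)


@pytest.fixture(scope="session")
def tiny_grid():
    return make_brain_grid((6, 6, 6), 8.0)


@pytest.fixture(scope="session")
def scenario_a_dataset(small_grid):
    return simulate_dataset(make_scenario("non_degenerate", seed=1, grid=small_grid))


@pytest.fixture(scope="session")
def scenario_b_dataset(small_grid):
    return simulate_dataset(make_scenario("by_condition", seed=1, grid=small_grid))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
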