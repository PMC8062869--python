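import numpy as np
import pytest

import lithospat as ls


@pytest.fixture(scope="session")
def small_scene():
    """Compact grain scene used across modules (fast to simulate)."""
    return ls.GrainScene(width_px=256, height_px=192, pixel_size_um=0.05,
                         seed=11)


@pytest.fixture(scope="session")
def small_map(small_scene):
    return ls.make_element_map(small_scene)


@pytest.fixture(scope="session")
def selective_pattern(small_map):
    """Pattern drawn from a strong planted S-selectivity (known truth)."""
    truth = ls.calibrate_beta0(small_map, {"S": 1.5}, 300)
    return ls.simulate_selective_cells(small_map, truth, seed=12), truth


@pytest.fixture(scope="session")
def unit_window():
    """Unit-area (1 um^2) fully valid window, 100x100 px."""
    return ls.ObservationWindow(100, 100, 0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
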