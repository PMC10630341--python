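import numpy as np
import pytest

from lenspol import SystemGeometry, scenes


@pytest.fixture(scope="session")
def small_geometry() -> SystemGeometry:
    """64x64 sensor, 3x3 LEDs: fast configuration for unit tests."""
    return SystemGeometry(led_grid=(3, 3), sensor_px=(64, 64))


@pytest.fixture(scope="session")
def small_mask():
    return scenes.random_binary_mask((64, 64), feature_px=8, open_ratio=0.5, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
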