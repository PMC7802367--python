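import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from micropat import CameraBackground, CameraModel

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

PIXEL_SIZE_UM = 0.11


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel(offset_mean=100.0, read_noise_sd=2.0, gain=1.0)


@pytest.fixture
def camera_bg(camera) -> CameraBackground:
    """The exact dark-signal statistics implied by the camera model."""
    return CameraBackground(camera.offset_mean, camera.read_noise_sd ** 2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
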