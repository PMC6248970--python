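import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radadapt import VolumeROI

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_roi(rng):
    """6^3 volume with an irregular ~90-voxel ROI."""
    vol = rng.normal(0, 10, (6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.5
    mask[2:4, 2:4, 2:4] = True  # keep it comfortably non-empty
    return VolumeROI(patient_id="small", volume=vol, mask=mask)


@pytest.fixture
def cube_roi(rng):
    """8^3 volume, fully masked, with alternating-slab texture plus noise."""
    vol = rng.normal(0, 1, (8, 8, 8))
    vol[::2] += 12.0
    mask = np.ones((8, 8, 8), dtype=bool)
    return VolumeROI(patient_id="cube", volume=vol, mask=mask)
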