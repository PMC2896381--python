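import numpy as np
import pytest

from voxscene import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_volume(rng):
    """A small random 8-bit volume with anisotropic calibration."""
    data = rng.integers(0, 256, size=(5, 6, 7), dtype=np.uint8).astype(np.uint8)
    return ImageVolume(data, calibration=(0.5, 0.5, 2.0))


@pytest.fixture
def smooth_volume(rng):
    """A smooth random phantom (Gaussian-filtered noise), good for
    interpolation-sensitive checks."""
    from scipy import ndimage

    raw = ndimage.gaussian_filter(rng.random((16, 16, 16)) * 255.0, sigma=2.0)
    return ImageVolume(np.clip(raw, 0, 255).astype(np.uint8))


@pytest.fixture
def asymmetric_volume():
    """A deliberately asymmetric phantom: renders differ under rotation."""
    data = np.zeros((8, 8, 8), dtype=np.uint8)
    data[1:4, 1:7, 1:3] = 200
    data[4:7, 5:7, 5:7] = 120
    data[0, 0, 0] = 255
    return ImageVolume(data)
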