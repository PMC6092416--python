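import numpy as np
import pytest

from deepfoci.image_model import TissueImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_peak_image():
    """Broad isotropic Gaussian peak centered in a 41x41 raster."""
    y, x = np.mgrid[0:41, 0:41]
    arr = 1000.0 * np.exp(-((x - 20) ** 2 + (y - 20) ** 2) / (2 * 8.0**2))
    return TissueImage(arr, saturation_value=65535.0)


@pytest.fixture
def five_peak_raster(rng):
    """Five well-separated equal peaks (amplitude 100) on sigma=1 noise."""
    y, x = np.mgrid[0:128, 0:128]
    arr = rng.normal(0.0, 1.0, (128, 128))
    for cx, cy in [(20, 20), (100, 20), (64, 64), (20, 100), (100, 100)]:
        arr += 100.0 * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / 40.0)
    return arr
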