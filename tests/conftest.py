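import numpy as np
import pytest

from puncta_ml.image_io import PixelScale


@pytest.fixture
def unit_scale() -> PixelScale:
    return PixelScale(1.0, 1.0)


@pytest.fixture
def confocal_scale() -> PixelScale:
    """A 101.6 um confocal field at 1024 px: ~0.0992 um/px."""
    return PixelScale(101.6 / 1024, 101.6 / 1024)


def gaussian_spot(shape, center, sigma, peak=1.0, background=0.0):
    """Noise-free isotropic Gaussian spot, clipped to [0, 1]."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = background + peak * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
    )
    return np.clip(img, 0.0, 1.0)
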