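import numpy as np
import pytest
from scipy import ndimage

from phasefuse.grid import ImageGrid


def make_plant_raster(n: int = 160, blur: float = 1.0) -> np.ndarray:
    """Sharp-edged asymmetric multi-ellipse fixture (plant-like content).

    Phase correlation needs broadband spectral content; filled ellipses with
    a light blur mimic leaf silhouettes without any randomness.
    """
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.zeros((n, n))
    shapes = [(0.50, 0.50, 0.21, 0.052, 0.3),
              (0.36, 0.62, 0.047, 0.125, -0.9),
              (0.65, 0.42, 0.083, 0.036, 1.2),
              (0.44, 0.34, 0.062, 0.062, 2.0),
              (0.62, 0.62, 0.036, 0.094, 0.7)]
    for (fy, fx, ry, rx, th) in shapes:
        cy, cx = fy * n, fx * n
        c, s = np.cos(th), np.sin(th)
        X = (xx - cx) * c + (yy - cy) * s
        Y = -(xx - cx) * s + (yy - cy) * c
        img[(X / (rx * n)) ** 2 + (Y / (ry * n)) ** 2 <= 1] = 0.9
    if blur:
        img = ndimage.gaussian_filter(img, blur)
    return img


@pytest.fixture(scope="session")
def plant_raster():
    return make_plant_raster(160)


@pytest.fixture(scope="session")
def plant_image(plant_raster):
    return ImageGrid(plant_raster, channel_kind="gray")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
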