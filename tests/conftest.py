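import numpy as np
import pytest

import hpwave as hw
from hpwave.reconstruction import GreenOperator, ImageGrid, MediumParameters


@pytest.fixture(scope="session")
def geo_small():
    """Coarse geometry (40 receivers, 11 frequencies) for fast tests."""
    return hw.make_geometry(rx_step=9.0, n_freq=11)


@pytest.fixture(scope="session")
def geo_default_coarse_freq():
    """Clinical angular sampling (80 rx, 10 tx) with a thinned frequency grid."""
    return hw.make_geometry(n_freq=16)


@pytest.fixture(scope="session")
def sigma_medium():
    return MediumParameters(relative_permittivity=1.0, conductivity=0.3)


@pytest.fixture(scope="session")
def grid64():
    return ImageGrid(half_extent=0.06, n_pixels_per_side=64)


@pytest.fixture(scope="session")
def matched_operator64(geo_default_coarse_freq, sigma_medium, grid64):
    """Shared back-propagation operator (kernel matched to 9-deg subtraction)."""
    return GreenOperator(geo_default_coarse_freq, sigma_medium, grid64, match_delta=9.0)


def reconstruct_phantom(phantom, geometry, operator, medium):
    """Forward-simulate (matched background), subtract, back-propagate."""
    sig = hw.simulate_s21(phantom, geometry, background=medium)
    return hw.huygens_reconstruct(hw.rotation_subtract(sig), operator=operator)


@pytest.fixture(scope="session")
def gaussian_image():
    """Unit-mean single-peak Gaussian intensity map on a fine masked grid."""
    grid = ImageGrid(half_extent=0.06, n_pixels_per_side=128)
    s = 8 * grid.pixel_spacing
    c = grid.pixel_centres
    x0, y0 = 0.012, -0.008
    intensity = np.exp(-((c[..., 0] - x0) ** 2 + (c[..., 1] - y0) ** 2) / (2 * s**2))
    intensity[~grid.breast_mask] = 0.0
    img = hw.MicrowaveImage(intensity, grid)
    return hw.normalize_mean1(img), s
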