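import numpy as np
import pytest

from spinequant import Image2D, PSFModel, SimulationConfig, SpineGeometry
from spinequant.psf import psf_profile
from spinequant.simulate import Emitter, GroundTruthSpine, render_image


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def geometry():
    return SpineGeometry()


@pytest.fixture
def sted_psf():
    return PSFModel("lorentzian", 40.0, 20.0, 11)


def make_spot_image(shape="lorentzian", fwhm_nm=40.0, pixel_size_nm=20.0,
                    field_px=64, amplitude=32.0, background=0.0,
                    offset_nm=(0.0, 0.0)):
    """Noiseless single-spot image with the emitter at the centre pixel's
    centre plus an optional sub-pixel offset; returns (image, (x, y))."""
    c = (field_px // 2 + 0.5) * pixel_size_nm
    x, y = c + offset_nm[0], c + offset_nm[1]
    xc = (np.arange(field_px) + 0.5) * pixel_size_nm
    xx, yy = np.meshgrid(xc, xc)
    r = np.hypot(xx - x, yy - y)
    pixels = background + amplitude * psf_profile(shape, fwhm_nm, r)
    return Image2D(pixels, pixel_size_nm, "A"), (x, y)


@pytest.fixture
def point_source_image():
    """Noiseless 40 nm Lorentzian point source at 20 nm pixels."""
    return make_spot_image()
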