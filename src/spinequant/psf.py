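"""Parametric point-spread functions and Richardson-Lucy deconvolution.

The effective STED focal spot is modelled as a 2-D radial Lorentzian,

    h(r) = gamma**2 / (r**2 + gamma**2),    gamma = FWHM / 2,

which reaches half its peak exactly at r = FWHM/2; the confocal alternative
is an isotropic Gaussian ``exp(-4 ln2 r**2 / FWHM**2)``.  Rendered kernels
are evaluated at pixel centres, truncated to a finite odd support and
normalised to unit sum.

Deconvolution is the classical multiplicative Richardson-Lucy scheme for
Poisson-noise images,

    f_{k+1} = f_k * [ (g / (f_k (*) h)) (*) h~ ],

where ``h~`` is the mirrored kernel, started from a flat image carrying the
same total flux.  Boundaries are handled reflectively so total flux is
conserved to well under 0.1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Image2D

__all__ = ["PSFModel", "render_psf", "psf_profile", "richardson_lucy"]

#: floor applied to the denominator of the RL ratio image
_DIVISION_EPS = 1e-12


@dataclass(frozen=True)
class PSFModel:
    """Parametric PSF: shape, width, and the raster it is rendered on.

    ``support`` is the odd kernel side length in pixels; the default 11 gives
    a ±100 nm window at 20 nm pixels, over five half-widths of a 40 nm core.
    """

    shape: str = "lorentzian"
    fwhm_nm: float = 40.0
    pixel_size_nm: float = 20.0
    support: int = 11

    def __post_init__(self) -> None:
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"shape must be 'lorentzian' or 'gaussian', got {self.shape!r}")
        if self.fwhm_nm <= 0:
            raise ValueError(f"fwhm_nm must be > 0, got {self.fwhm_nm}")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if self.support < 3 or self.support % 2 == 0:
            raise ValueError(f"support must be odd and >= 3, got {self.support}")


def psf_profile(shape: str, fwhm_nm: float, r_nm: np.ndarray | float) -> np.ndarray:
    """Unnormalised radial profile with peak value 1 at r = 0.

    By construction the profile equals 0.5 at ``r = fwhm_nm / 2`` for both
    supported shapes.
    """
    r2 = np.square(np.asarray(r_nm, dtype=float))
    if shape == "lorentzian":
        gamma = fwhm_nm / 2.0
        return gamma**2 / (r2 + gamma**2)
    if shape == "gaussian":
        return np.exp(-4.0 * np.log(2.0) * r2 / fwhm_nm**2)
    raise ValueError(f"unknown PSF shape {shape!r}")


def render_psf(model: PSFModel) -> np.ndarray:
    """Render the PSF to a unit-sum kernel of side ``model.support``.

    The profile is evaluated at pixel centres relative to the central pixel;
    truncated tails are folded into the normalisation.
    """
    c = model.support // 2
    idx = np.arange(model.support) - c
    r_nm = model.pixel_size_nm * np.hypot(*np.meshgrid(idx, idx, indexing="ij"))
    kernel = psf_profile(model.shape, model.fwhm_nm, r_nm)
    return kernel / kernel.sum()


def richardson_lucy(image: Image2D, model: PSFModel, iterations: int = 20) -> Image2D:
    """Richardson-Lucy deconvolution of a count image.

    Parameters
    ----------
    image
        Raw count image; its pixel size must match the PSF model's.
    model
        PSF to deconvolve with.
    iterations
        Number of multiplicative updates (>= 1); 20 by default.

    Returns
    -------
    Image2D
        Non-negative estimate with the input's total flux preserved to
        better than 0.1%.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    if not np.isclose(image.pixel_size_nm, model.pixel_size_nm):
        raise ValueError(
            f"pixel-size mismatch: image {image.pixel_size_nm} nm vs "
            f"PSF {model.pixel_size_nm} nm")

    data = image.pixels
    total = data.sum()
    if total == 0:
        warnings.warn("richardson_lucy: all-zero image returned unchanged")
        return image.copy()

    kernel = render_psf(model)
    # flat start with the same total flux
    estimate = np.full_like(data, data.mean())
    for _ in range(iterations):
        blurred = ndimage.convolve(estimate, kernel, mode="reflect")
        ratio = data / np.maximum(blurred, _DIVISION_EPS)
        # correlate == convolve with the mirrored kernel
        estimate = estimate * ndimage.correlate(ratio, kernel, mode="reflect")
        np.maximum(estimate, 0.0, out=estimate)
    return Image2D(estimate, image.pixel_size_nm, image.channel)
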