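"""Nanocluster detection and 20-angle FWHM sizing.

Each labelled protein cluster is located as the centre of its emission
profile: a local intensity maximum above a robust noise threshold, refined
to sub-pixel precision by an intensity-weighted centroid.  Cluster size is
the mean full width at half maximum of line profiles taken through the
centre at angles evenly spaced over a half turn (each profile covers both
directions, so [0, pi) avoids duplicating diameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import disk

from .image import Image2D

__all__ = ["Cluster", "detect_clusters", "measure_fwhm", "peak_intensity",
           "size_clusters", "estimate_background"]


@dataclass
class Cluster:
    """One detected emission profile.

    ``fwhm_nm`` is the arithmetic mean of the finite entries of
    ``per_angle_fwhm``; angles whose profile never drops below half maximum
    contribute NaN and raise the ``fit_failed`` flag.
    """

    x_nm: float
    y_nm: float
    peak_counts: float
    fwhm_nm: float = float("nan")
    per_angle_fwhm: list[float] = field(default_factory=list)
    channel: str = ""
    flags: set[str] = field(default_factory=set)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_nm, self.y_nm)


def estimate_background(image: Image2D) -> tuple[float, float]:
    """Robust (background, noise-scale) estimate for a sparse-signal image.

    The median is dominated by non-spine pixels; the noise scale is the
    Gaussian-consistent MAD (1.4826 * median absolute deviation).
    """
    flat = image.pixels.ravel()
    bg = float(np.median(flat))
    mad = float(np.median(np.abs(flat - bg)))
    return bg, 1.4826 * mad


def _bilinear(image: Image2D, x_nm: np.ndarray, y_nm: np.ndarray,
              mode: str = "nearest") -> np.ndarray:
    """Bilinear interpolation at physical positions (pixel-centre convention)."""
    p = image.pixel_size_nm
    rows = np.asarray(y_nm, dtype=float) / p - 0.5
    cols = np.asarray(x_nm, dtype=float) / p - 0.5
    return ndimage.map_coordinates(image.pixels, [rows, cols], order=1, mode=mode)


def peak_intensity(image: Image2D, center_xy: tuple[float, float]) -> float:
    """Bilinearly interpolated count value at a physical position.

    Intended for reading calibrated peak brightness off the *raw* image,
    where counts keep their detector meaning.
    """
    x, y = center_xy
    w, h = image.extent_nm
    if not (0 <= x <= w and 0 <= y <= h):
        raise ValueError(f"center ({x:.1f}, {y:.1f}) nm outside image bounds "
                         f"({w:.0f} x {h:.0f} nm)")
    return float(_bilinear(image, np.array([x]), np.array([y]))[0])


def detect_clusters(image: Image2D, min_peak_snr: float = 5.0,
                    min_separation_nm: float = 60.0,
                    centroid_window_px: int = 5) -> list[Cluster]:
    """Find cluster centres as thresholded local maxima with centroid refinement.

    Parameters
    ----------
    image
        Deconvolved (or raw) image.
    min_peak_snr
        Peaks must exceed ``background + min_peak_snr * noise_scale`` where
        both terms come from :func:`estimate_background`.
    min_separation_nm
        Minimum Euclidean centre-to-centre distance between accepted
        maxima (the dimmer of two closer maxima is suppressed); must be at
        least one pixel.  The 60 nm default treats sub-structure within
        one cluster-sized profile as a single cluster; for spacing
        analyses near the resolution limit, 40 nm — the resolution floor
        of the deconvolved data — avoids truncating the distance
        distribution.
    centroid_window_px
        Odd side length of the window used for the intensity-weighted
        centroid refinement.

    Returns
    -------
    list of Cluster
        Centres and interpolated peak counts only; sizes are filled in by
        :func:`measure_fwhm`.  An empty list is a valid result.
    """
    p = image.pixel_size_nm
    if min_separation_nm < p:
        raise ValueError("min_separation_nm must be >= pixel_size")
    bg, noise = estimate_background(image)
    threshold = bg + min_peak_snr * noise
    min_dist_px = max(1, int(round(min_separation_nm / p)))
    # disk footprint: Euclidean exclusion radius (min_distance alone would
    # impose a square, i.e. Chebyshev, exclusion zone)
    coords = peak_local_max(image.pixels, footprint=disk(min_dist_px),
                            threshold_abs=threshold, exclude_border=False)

    half = centroid_window_px // 2
    h, w = image.pixels.shape
    clusters: list[Cluster] = []
    for row, col in coords:
        r0, r1 = max(0, row - half), min(h, row + half + 1)
        c0, c1 = max(0, col - half), min(w, col + half + 1)
        window = np.clip(image.pixels[r0:r1, c0:c1] - bg, 0.0, None)
        flags: set[str] = set()
        if window.sum() > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            row_c = float((window * rr).sum() / window.sum())
            col_c = float((window * cc).sum() / window.sum())
        else:  # flat window: keep the raster maximum
            row_c, col_c = float(row), float(col)
        if row - half < 0 or row + half >= h or col - half < 0 or col + half >= w:
            flags.add("edge_truncated")
        x_nm, y_nm = (col_c + 0.5) * p, (row_c + 0.5) * p
        peak = float(_bilinear(image, np.array([x_nm]), np.array([y_nm]))[0])
        clusters.append(Cluster(x_nm=x_nm, y_nm=y_nm, peak_counts=peak,
                                channel=image.channel, flags=flags))
    clusters.sort(key=lambda c: (c.y_nm, c.x_nm))
    return clusters


def measure_fwhm(image: Image2D, center_xy: tuple[float, float],
                 n_angles: int = 20, half_length_nm: float = 200.0,
                 background: float | None = None,
                 step_nm: float | None = None) -> tuple[float, list[float]]:
    """Mean FWHM of line profiles through a centre over ``n_angles`` angles.

    For each angle in ``[0, pi)`` the profile is sampled by cubic-spline
    interpolation at ``step_nm`` spacing (default pixel_size / 4) out to
    ``half_length_nm`` on both sides.  (Cubic rather than bilinear: linear
    interpolation between 20 nm samples systematically narrows a sharply
    peaked profile by ~3 nm at the 40 nm resolution floor.)  The half level
    is ``background + (peak - background) / 2`` with the peak read from the
    same interpolant at the centre; walking outward from the peak, the
    first crossing on each side is located by linear interpolation between
    samples and the per-angle FWHM is the distance between the two
    crossings.  Angles with no crossing yield NaN.

    Returns
    -------
    (fwhm_nm, per_angle)
        Mean over the finite per-angle values, and the full list.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    x0, y0 = center_xy
    p = image.pixel_size_nm
    step = p / 4.0 if step_nm is None else step_nm
    if background is None:
        background = estimate_background(image)[0]

    coeffs = ndimage.spline_filter(image.pixels, order=3, mode="mirror")

    def sample(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(coeffs, [ys / p - 0.5, xs / p - 0.5],
                                       order=3, prefilter=False, mode="mirror")

    peak = float(sample(np.array([x0]), np.array([y0]))[0])
    half_level = background + (peak - background) / 2.0

    t = np.arange(0.0, half_length_nm + step / 2, step)  # one-sided offsets
    per_angle: list[float] = []
    for theta in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        dx, dy = np.cos(theta), np.sin(theta)
        widths = []
        for sign in (+1.0, -1.0):
            xs = x0 + sign * t * dx
            ys = y0 + sign * t * dy
            vals = sample(xs, ys)
            below = np.nonzero(vals < half_level)[0]
            if below.size == 0 or below[0] == 0:
                widths.append(np.nan)
                continue
            k = below[0]
            v0, v1 = vals[k - 1], vals[k]
            frac = (v0 - half_level) / (v0 - v1) if v1 != v0 else 0.0
            widths.append((k - 1 + frac) * step)
        per_angle.append(float(widths[0] + widths[1]))

    arr = np.asarray(per_angle)
    finite = arr[np.isfinite(arr)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return mean, per_angle


def size_clusters(image: Image2D, clusters: list[Cluster], n_angles: int = 20,
                  half_length_nm: float = 200.0,
                  background: float | None = None) -> list[Cluster]:
    """Fill in FWHM sizes for detected clusters, flagging failed angles."""
    if background is None:
        background = estimate_background(image)[0]
    for c in clusters:
        fwhm, per_angle = measure_fwhm(image, c.center, n_angles=n_angles,
                                       half_length_nm=half_length_nm,
                                       background=background)
        c.fwhm_nm = fwhm
        c.per_angle_fwhm = per_angle
        if any(not np.isfinite(v) for v in per_angle):
            c.flags.add("fit_failed")
    return clusters
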