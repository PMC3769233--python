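"""Stoichiometry and copy-number estimation.

Two independent routes to "how many protein copies sit in a spine":

1. brightness ratio — compare the mean peak intensity of in-spine clusters
   with that of isolated single-antibody spots on glass; the ratio counts
   labelled immunocomplexes per cluster.
2. geometry x concentration — model the spine as a spherical head of
   diameter D plus a cylindrical neck of length L and width w, and multiply
   the volume by an assumed bulk concentration and Avogadro's number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import Cluster
from .simulate import SpineGeometry

__all__ = ["AVOGADRO", "CopyNumberEstimate", "brightness_ratio", "spine_volume",
           "copies_from_concentration", "copies_per_spine_from_imaging"]

AVOGADRO = 6.02214076e23  # mol^-1

NM3_PER_LITER = 1e24  # 1 L = 1e24 nm^3


@dataclass
class CopyNumberEstimate:
    brightness_ratio: float
    complexes_per_cluster: float
    spine_volume_L: float
    copies_from_concentration: int
    head_diameter_nm: float
    neck_length_nm: float
    neck_width_nm: float
    concentration_M: float


def brightness_ratio(cluster_peaks, reference_peaks):
    """Ratio of mean cluster peak intensity to mean single-spot reference peak.

    Returns ``(ratio, (mean_c, mean_r), (sd_c, sd_r), (n_c, n_r))``; SDs use
    the n-1 denominator (0 for a single value).
    """
    c = np.asarray(cluster_peaks, dtype=float)
    r = np.asarray(reference_peaks, dtype=float)
    if c.size == 0 or r.size == 0:
        raise ValueError("brightness_ratio: empty peak list")
    if np.any(c <= 0) or np.any(r <= 0):
        raise ValueError("brightness_ratio: peaks must be positive")
    if r.mean() <= 0:
        raise ValueError("brightness_ratio: non-positive reference mean")
    sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
    return (float(c.mean() / r.mean()), (float(c.mean()), float(r.mean())),
            (sd(c), sd(r)), (int(c.size), int(r.size)))


def spine_volume(geometry: "SpineGeometry | tuple[float, float, float]") -> float:
    """Spine volume in litres: sphere head + cylinder neck.

    V = (pi/6) D^3 + pi (w/2)^2 L, dimensions in nm, converted at
    1 nm^3 = 1e-24 L.  Accepts a :class:`SpineGeometry` or a raw
    ``(D, L, w)`` tuple; the tuple form permits the degenerate D = 0
    bare-cylinder case.  Negative dimensions are rejected.
    """
    if isinstance(geometry, SpineGeometry):
        D, L, w = (geometry.head_diameter_nm, geometry.neck_length_nm,
                   geometry.neck_width_nm)
    else:
        D, L, w = geometry
    if D < 0 or L <= 0 or w <= 0:
        raise ValueError("spine_volume: dimensions must be positive")
    v_nm3 = (np.pi / 6.0) * D**3 + np.pi * (w / 2.0) ** 2 * L
    return float(v_nm3 / NM3_PER_LITER)


def copies_from_concentration(volume_L: float, concentration_M: float) -> int:
    """Copy number = volume x concentration x Avogadro, nearest integer."""
    if volume_L <= 0:
        raise ValueError("volume_L must be > 0")
    if concentration_M < 0:
        raise ValueError("concentration_M must be >= 0")
    return int(round(volume_L * concentration_M * AVOGADRO))


def copies_per_spine_from_imaging(clusters: list[Cluster], reference_peaks):
    """Labelled-complex count per spine from per-cluster peak ratios.

    Each cluster's complex count is its peak divided by the mean reference
    peak, rounded and clamped at 1 (a detected cluster holds at least one
    complex); the spine total is the sum.  The unlabeled fraction is
    unknown, so this is a lower bound on true copy number.

    Returns a dict with per-cluster counts, the spine total, and flags.
    """
    if len(clusters) < 1:
        raise ValueError("copies_per_spine_from_imaging: need >= 1 cluster")
    ref = np.asarray(reference_peaks, dtype=float)
    if ref.size == 0 or ref.mean() <= 0:
        raise ValueError("copies_per_spine_from_imaging: bad reference peaks")
    ref_mean = ref.mean()
    per_cluster = []
    flags = {"unlabeled_fraction_unknown"}
    for c in clusters:
        count = int(round(c.peak_counts / ref_mean))
        if count < 1:
            count = 1
            flags.add("clamped_to_one")
        per_cluster.append(count)
    return {"per_cluster_counts": per_cluster,
            "spine_total": int(sum(per_cluster)),
            "reference_mean": float(ref_mean),
            "flags": flags}
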