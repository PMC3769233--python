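"""Ground-truth simulator for two-color STED images of dendritic spines.

The forward model emulates what the analysis assumes about the real data:

* a mushroom spine projected to 2-D — a circular head (diameter ~300 nm)
  attached to a rectangular neck (~300 x 100 nm);
* a couple of nanoclusters per spine, each a handful of immunocomplexes
  drawn uniformly from a disc whose diameter is the cluster's ground-truth
  extent (the FWHM of the emitter-density profile);
* an antibody linkage error displacing every label by a random 15-20 nm in
  a uniform direction;
* image formation as a sum of per-emitter PSF profiles (40 nm Lorentzian
  for STED, ~250 nm Gaussian for confocal) scaled so one isolated
  immunocomplex peaks at ~32 counts, plus a flat background and per-pixel
  Poisson noise;
* 20 nm pixels.

Everything is driven by ``numpy.random.Generator`` streams, so a fixed seed
gives bit-identical images and truth tables.  Ground truth is produced
alongside images; the analysis modules never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .image import Image2D
from .psf import PSFModel, psf_profile

__all__ = [
    "SpineGeometry", "GroundTruthCluster", "Emitter", "GroundTruthSpine",
    "SimulationConfig", "make_spine_mask", "spine_origin", "point_in_spine",
    "place_clusters", "place_cluster_pair", "render_image",
    "simulate_dual_color", "simulate_glass_spots", "lognormal_brightness",
    "truncated_normal",
]

_MAX_RETRIES = 1000


@dataclass(frozen=True)
class SpineGeometry:
    """Mushroom-spine 2-D projection: head disc plus axis-aligned neck.

    The neck rectangle starts at the rightmost point of the head disc, so
    head and neck areas are disjoint and the total area is exactly
    ``pi (D/2)^2 + L w``.
    """

    head_diameter_nm: float = 300.0
    neck_length_nm: float = 300.0
    neck_width_nm: float = 100.0

    def __post_init__(self) -> None:
        if min(self.head_diameter_nm, self.neck_length_nm, self.neck_width_nm) <= 0:
            raise ValueError("spine dimensions must be > 0")
        if self.head_diameter_nm < self.neck_width_nm:
            raise ValueError("head_diameter_nm must be >= neck_width_nm")

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Bounding-box (width, height) of the projection."""
        return (self.head_diameter_nm + self.neck_length_nm,
                max(self.head_diameter_nm, self.neck_width_nm))

    @property
    def area_nm2(self) -> float:
        return (np.pi * (self.head_diameter_nm / 2.0) ** 2
                + self.neck_length_nm * self.neck_width_nm)


@dataclass
class GroundTruthCluster:
    channel: str
    cluster_id: int
    x_nm: float
    y_nm: float
    extent_fwhm_nm: float
    n_complexes: int
    realized_cross_nn_nm: float = float("nan")


@dataclass
class Emitter:
    channel: str
    cluster_id: int
    x_nm: float
    y_nm: float
    brightness: float  # expected isolated peak counts


@dataclass
class GroundTruthSpine:
    """Simulator truth: geometry, its placement, clusters, and emitters."""

    geometry: SpineGeometry
    origin_xy_nm: tuple[float, float]  # head-disc centre in field coordinates
    clusters: list[GroundTruthCluster] = field(default_factory=list)
    emitters: list[Emitter] = field(default_factory=list)

    def cluster_centers(self, channel: str) -> np.ndarray:
        return np.array([[c.x_nm, c.y_nm] for c in self.clusters
                         if c.channel == channel]).reshape(-1, 2)

    def truth_table(self, spine_id: int = 0) -> pd.DataFrame:
        rows = [{"spine_id": spine_id, "channel": c.channel,
                 "cluster_id": c.cluster_id, "x_nm": c.x_nm, "y_nm": c.y_nm,
                 "extent_fwhm_nm": c.extent_fwhm_nm,
                 "n_complexes": c.n_complexes,
                 "realized_cross_nn_nm": c.realized_cross_nn_nm}
                for c in self.clusters]
        return pd.DataFrame(rows)


@dataclass
class SimulationConfig:
    """Acquisition settings of the virtual microscope.

    ``single_complex_peak`` / ``single_complex_sd`` set the lognormal
    brightness of one immunocomplex, in expected isolated-spot peak counts;
    ``linkage_offset_nm`` is the (min, max) magnitude of the antibody
    linkage displacement.
    """

    pixel_size_nm: float = 20.0
    field_size_px: int = 64
    psf: PSFModel = field(default_factory=PSFModel)
    background: float = 2.0
    single_complex_peak: float = 32.0
    single_complex_sd: float = 12.0
    linkage_offset_nm: tuple[float, float] = (15.0, 20.0)
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.single_complex_peak <= 0:
            raise ValueError("single_complex_peak must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# distributions

def lognormal_brightness(mean: float, sd: float) -> Callable[[np.random.Generator], float]:
    """Lognormal brightness sampler with the given mean and SD (SD=0 → constant)."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0, sd >= 0")
    if sd == 0:
        return lambda rng: mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    sigma = np.sqrt(sigma2)
    return lambda rng: float(rng.lognormal(mu, sigma))


def truncated_normal(mean: float, sd: float, low: float = 0.0
                     ) -> Callable[[np.random.Generator], float]:
    """Rejection sampler for a normal truncated below at ``low``."""

    def draw(rng: np.random.Generator) -> float:
        for _ in range(_MAX_RETRIES):
            x = rng.normal(mean, sd)
            if x >= low:
                return float(x)
        raise RuntimeError("truncated_normal: rejection sampling failed")

    return draw


def _as_sampler(dist) -> Callable[[np.random.Generator], float]:
    if callable(dist):
        return dist
    return lambda rng, _v=float(dist): _v


# ---------------------------------------------------------------------------
# geometry

def spine_origin(geometry: SpineGeometry, pixel_size_nm: float,
                 field_size_px: int | tuple[int, int]) -> tuple[float, float]:
    """Head-disc centre that centres the spine's bounding box in the field."""
    if isinstance(field_size_px, int):
        field_size_px = (field_size_px, field_size_px)
    h_px, w_px = field_size_px
    field_w, field_h = w_px * pixel_size_nm, h_px * pixel_size_nm
    span_x, span_y = geometry.extent_nm
    if span_x > field_w or span_y > field_h:
        raise ValueError(
            f"spine ({span_x:.0f} x {span_y:.0f} nm) does not fit in field "
            f"({field_w:.0f} x {field_h:.0f} nm)")
    x0 = (field_w - span_x) / 2.0 + geometry.head_diameter_nm / 2.0
    y0 = field_h / 2.0
    return (x0, y0)


def point_in_spine(geometry: SpineGeometry, origin_xy_nm: tuple[float, float],
                   x_nm, y_nm):
    """Vectorised membership test for the head-disc ∪ neck-rectangle region.

    The neck intervals are half-open so that a rasterised boundary lying
    exactly on pixel centres is counted once, not on both edges.
    """
    x0, y0 = origin_xy_nm
    x = np.asarray(x_nm, dtype=float)
    y = np.asarray(y_nm, dtype=float)
    r_head = geometry.head_diameter_nm / 2.0
    in_head = (x - x0) ** 2 + (y - y0) ** 2 <= r_head**2
    neck_x0 = x0 + r_head
    in_neck = ((x >= neck_x0) & (x < neck_x0 + geometry.neck_length_nm)
               & (y >= y0 - geometry.neck_width_nm / 2.0)
               & (y < y0 + geometry.neck_width_nm / 2.0))
    return in_head | in_neck


def make_spine_mask(geometry: SpineGeometry, pixel_size_nm: float,
                    field_size_px: int | tuple[int, int]) -> np.ndarray:
    """Binary raster of the spine region (pixel centres inside it)."""
    if isinstance(field_size_px, int):
        field_size_px = (field_size_px, field_size_px)
    origin = spine_origin(geometry, pixel_size_nm, field_size_px)
    h_px, w_px = field_size_px
    xc = (np.arange(w_px) + 0.5) * pixel_size_nm
    yc = (np.arange(h_px) + 0.5) * pixel_size_nm
    xx, yy = np.meshgrid(xc, yc)
    return point_in_spine(geometry, origin, xx, yy)


def _sample_point_in_spine(geometry: SpineGeometry, origin: tuple[float, float],
                           rng: np.random.Generator,
                           head_bias: float | None = None) -> tuple[float, float]:
    """Uniform point in the spine region; ``head_bias`` overrides the
    area-proportional head probability."""
    x0, y0 = origin
    r_head = geometry.head_diameter_nm / 2.0
    a_head = np.pi * r_head**2
    p_head = a_head / geometry.area_nm2 if head_bias is None else head_bias
    if rng.uniform() < p_head:
        r = r_head * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        return (x0 + r * np.cos(th), y0 + r * np.sin(th))
    x = x0 + r_head + rng.uniform(0, geometry.neck_length_nm)
    y = y0 + rng.uniform(-0.5, 0.5) * geometry.neck_width_nm
    return (x, y)


# ---------------------------------------------------------------------------
# cluster and emitter placement

def _populate_emitters(truth: GroundTruthSpine, cluster: GroundTruthCluster,
                       rng: np.random.Generator,
                       linkage_offset_nm: tuple[float, float],
                       brightness: Callable[[np.random.Generator], float]) -> None:
    """Draw the cluster's immunocomplex labels: uniform in the extent disc,
    each displaced by a linkage offset, rejected until inside the spine."""
    radius = cluster.extent_fwhm_nm / 2.0
    lo, hi = linkage_offset_nm
    for _ in range(cluster.n_complexes):
        for _ in range(_MAX_RETRIES):
            r = radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x = cluster.x_nm + r * np.cos(th)
            y = cluster.y_nm + r * np.sin(th)
            if hi > 0:
                off = rng.uniform(lo, hi)
                phi = rng.uniform(0, 2 * np.pi)
                x += off * np.cos(phi)
                y += off * np.sin(phi)
            if point_in_spine(truth.geometry, truth.origin_xy_nm, x, y):
                break
        else:
            raise RuntimeError(
                "emitter placement failed: could not keep an emitter inside "
                "the spine mask after bounded retries")
        truth.emitters.append(Emitter(cluster.channel, cluster.cluster_id,
                                      float(x), float(y), brightness(rng)))


def place_clusters(geometry: SpineGeometry, n_clusters: int, extent_dist,
                   complexes_dist, rng: np.random.Generator, *,
                   origin_xy_nm: tuple[float, float] | None = None,
                   pixel_size_nm: float = 20.0,
                   field_size_px: int | tuple[int, int] = 64,
                   min_separation_nm: float = 0.0,
                   linkage_offset_nm: tuple[float, float] = (15.0, 20.0),
                   brightness=None, channel: str = "A",
                   head_bias: float | None = None) -> GroundTruthSpine:
    """Place ``n_clusters`` nanoclusters uniformly over the spine region.

    ``extent_dist`` and ``complexes_dist`` may be scalars or callables
    taking a Generator; ``min_separation_nm`` enforces a minimum pairwise
    centre distance by rejection (bounded retries).
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if origin_xy_nm is None:
        origin_xy_nm = spine_origin(geometry, pixel_size_nm, field_size_px)
    truth = GroundTruthSpine(geometry, origin_xy_nm)
    extent = _as_sampler(extent_dist)
    complexes = _as_sampler(complexes_dist)
    if brightness is None:
        brightness = lognormal_brightness(32.0, 12.0)

    centers: list[tuple[float, float]] = []
    for k in range(n_clusters):
        for _ in range(_MAX_RETRIES):
            pt = _sample_point_in_spine(geometry, origin_xy_nm, rng, head_bias)
            if all(np.hypot(pt[0] - cx, pt[1] - cy) >= min_separation_nm
                   for cx, cy in centers):
                break
        else:
            raise RuntimeError(
                f"cluster placement failed: min_separation_nm="
                f"{min_separation_nm} infeasible after {_MAX_RETRIES} retries")
        centers.append(pt)
        cl = GroundTruthCluster(channel, k, pt[0], pt[1],
                                float(extent(rng)),
                                max(1, int(round(complexes(rng)))))
        truth.clusters.append(cl)
        _populate_emitters(truth, cl, rng, linkage_offset_nm, brightness)
    return truth


def place_cluster_pair(geometry: SpineGeometry, separation_dist,
                       extent_dist, complexes_dist, rng: np.random.Generator, *,
                       origin_xy_nm: tuple[float, float] | None = None,
                       pixel_size_nm: float = 20.0,
                       field_size_px: int | tuple[int, int] = 64,
                       linkage_offset_nm: tuple[float, float] = (15.0, 20.0),
                       brightness=None, channel: str = "A") -> GroundTruthSpine:
    """Place exactly two clusters whose centre separation is drawn from
    ``separation_dist`` — the pair realises that nearest-neighbor distance
    exactly, which makes spacing-recovery experiments well-posed.
    """
    if origin_xy_nm is None:
        origin_xy_nm = spine_origin(geometry, pixel_size_nm, field_size_px)
    extent = _as_sampler(extent_dist)
    complexes = _as_sampler(complexes_dist)
    sep = _as_sampler(separation_dist)
    if brightness is None:
        brightness = lognormal_brightness(32.0, 12.0)

    d = float(sep(rng))
    for _ in range(_MAX_RETRIES):
        p1 = _sample_point_in_spine(geometry, origin_xy_nm, rng)
        th = rng.uniform(0, 2 * np.pi)
        p2 = (p1[0] + d * np.cos(th), p1[1] + d * np.sin(th))
        if point_in_spine(geometry, origin_xy_nm, *p2):
            break
    else:
        raise RuntimeError(
            f"pair placement failed: separation {d:.0f} nm does not fit the "
            "spine after bounded retries")
    truth = GroundTruthSpine(geometry, origin_xy_nm)
    for k, pt in enumerate((p1, p2)):
        cl = GroundTruthCluster(channel, k, pt[0], pt[1], float(extent(rng)),
                                max(1, int(round(complexes(rng)))))
        truth.clusters.append(cl)
        _populate_emitters(truth, cl, rng, linkage_offset_nm, brightness)
    return truth


def simulate_dual_color(geometry: SpineGeometry, n_a: int, n_b: int,
                        cross_nn_dist, extent_dist, complexes_dist,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None, *,
                        channel_a: str = "A", channel_b: str = "B",
                        b_head_bias: float = 0.8,
                        min_separation_a_nm: float = 60.0,
                        render: bool = True,
                        ) -> tuple[Image2D | None, Image2D | None, GroundTruthSpine]:
    """Two-channel spine with controlled A→nearest-B distances.

    Channel-B clusters are placed first, biased toward the spine head
    (probability ``b_head_bias``); each channel-A cluster is then placed so
    its distance to the *nearest* B cluster equals a draw from
    ``cross_nn_dist`` (rejection keeps it inside the spine and keeps A
    clusters ``min_separation_a_nm`` apart).  Realised distances are stored
    in the ground-truth table.
    """
    if rng is None:
        rng = config.rng()
    origin = spine_origin(geometry, config.pixel_size_nm, config.field_size_px)
    brightness = lognormal_brightness(config.single_complex_peak,
                                      config.single_complex_sd)
    extent = _as_sampler(extent_dist)
    complexes = _as_sampler(complexes_dist)
    cross = _as_sampler(cross_nn_dist)

    truth = GroundTruthSpine(geometry, origin)
    b_centers: list[tuple[float, float]] = []
    for k in range(n_b):
        for _ in range(_MAX_RETRIES):
            pt = _sample_point_in_spine(geometry, origin, rng, head_bias=b_head_bias)
            if all(np.hypot(pt[0] - cx, pt[1] - cy) >= min_separation_a_nm
                   for cx, cy in b_centers):
                break
        else:
            raise RuntimeError("channel-B cluster placement failed after retries")
        b_centers.append(pt)
        cl = GroundTruthCluster(channel_b, k, pt[0], pt[1], float(extent(rng)),
                                max(1, int(round(complexes(rng)))))
        truth.clusters.append(cl)
        _populate_emitters(truth, cl, rng, config.linkage_offset_nm, brightness)

    b_arr = np.array(b_centers)
    a_centers: list[tuple[float, float]] = []
    for k in range(n_a):
        d = float(cross(rng))
        if d < 0:
            raise ValueError("cross_nn_dist must be non-negative")
        placed = False
        for _ in range(_MAX_RETRIES):
            ref = b_centers[rng.integers(len(b_centers))]
            th = rng.uniform(0, 2 * np.pi)
            pt = (ref[0] + d * np.cos(th), ref[1] + d * np.sin(th))
            if not point_in_spine(geometry, origin, *pt):
                continue
            nn_b = float(np.min(np.hypot(b_arr[:, 0] - pt[0], b_arr[:, 1] - pt[1])))
            if nn_b < d - 1e-6:  # another B cluster would be closer
                continue
            if any(np.hypot(pt[0] - ax, pt[1] - ay) < min_separation_a_nm
                   for ax, ay in a_centers):
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"channel-A placement failed: cross distance {d:.0f} nm "
                "not realisable after bounded retries")
        a_centers.append(pt)
        cl = GroundTruthCluster(channel_a, k, pt[0], pt[1], float(extent(rng)),
                                max(1, int(round(complexes(rng)))),
                                realized_cross_nn_nm=nn_b)
        truth.clusters.append(cl)
        _populate_emitters(truth, cl, rng, config.linkage_offset_nm, brightness)

    if not render:
        return None, None, truth
    img_a = render_image(truth, config, channel_a, rng=rng)
    img_b = render_image(truth, config, channel_b, rng=rng)
    return img_a, img_b, truth


# ---------------------------------------------------------------------------
# rendering

def render_image(truth: GroundTruthSpine, config: SimulationConfig,
                 channel: str,
                 rng: np.random.Generator | None = None) -> Image2D:
    """Render one channel: sum of per-emitter PSF profiles plus background.

    Each emitter contributes ``brightness * h(r)`` with the PSF profile
    normalised to peak 1, so an isolated single complex peaks at its drawn
    brightness (up to pixel discretisation).  Per-pixel Poisson noise is
    applied when ``config.noise == 'poisson'``.
    """
    labels = {e.channel for e in truth.emitters} | {c.channel for c in truth.clusters}
    if truth.clusters and channel not in labels:
        raise ValueError(f"channel {channel!r} not present in ground truth {sorted(labels)}")
    if rng is None:
        rng = config.rng()
    n = config.field_size_px
    shape = (n, n) if isinstance(n, int) else n
    p = config.pixel_size_nm
    xc = (np.arange(shape[1]) + 0.5) * p
    yc = (np.arange(shape[0]) + 0.5) * p
    xx, yy = np.meshgrid(xc, yc)
    expected = np.full(shape, float(config.background))
    for e in truth.emitters:
        if e.channel != channel:
            continue
        r = np.hypot(xx - e.x_nm, yy - e.y_nm)
        expected += e.brightness * psf_profile(config.psf.shape,
                                              config.psf.fwhm_nm, r)
    if config.noise == "poisson":
        pixels = rng.poisson(expected).astype(float)
    else:
        pixels = expected
    return Image2D(pixels, p, channel)


def simulate_glass_spots(n: int, config: SimulationConfig,
                         rng: np.random.Generator | None = None, *,
                         min_separation_nm: float = 300.0,
                         margin_nm: float = 150.0
                         ) -> tuple[Image2D, pd.DataFrame]:
    """Isolated single-antibody spots on bare glass, for brightness calibration.

    Spot brightness is lognormal with mean ``single_complex_peak`` and SD
    ``single_complex_sd``.  Returns the image and a truth table with columns
    spot_id, x_nm, y_nm, brightness.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = config.rng()
    size = config.field_size_px
    shape = (size, size) if isinstance(size, int) else size
    p = config.pixel_size_nm
    w, h = shape[1] * p, shape[0] * p
    brightness = lognormal_brightness(config.single_complex_peak,
                                      config.single_complex_sd)
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        for _ in range(_MAX_RETRIES):
            pt = (rng.uniform(margin_nm, w - margin_nm),
                  rng.uniform(margin_nm, h - margin_nm))
            if all(np.hypot(pt[0] - x, pt[1] - y) >= min_separation_nm
                   for x, y in pts):
                break
        else:
            raise RuntimeError(
                f"glass-spot placement failed: {n} spots at >= "
                f"{min_separation_nm} nm separation do not fit the field")
        pts.append(pt)

    # emitters on glass: no spine, no clusters
    geometry = SpineGeometry()
    truth = GroundTruthSpine(geometry, (0.0, 0.0))
    rows = []
    for i, (x, y) in enumerate(pts):
        b = brightness(rng)
        truth.emitters.append(Emitter("glass", i, x, y, b))
        rows.append({"spot_id": i, "x_nm": x, "y_nm": y, "brightness": b})
    img = render_image(truth, config, "glass", rng=rng) if pts else Image2D(
        rng.poisson(config.background, shape).astype(float)
        if config.noise == "poisson" else np.full(shape, float(config.background)),
        p, "glass")
    return img, pd.DataFrame(rows, columns=["spot_id", "x_nm", "y_nm", "brightness"])
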