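"""Nearest-neighbor distance analysis within and across channels.

Distances are always computed per image (per spine) and only pooled across
images afterwards — nearest neighbors across disjoint fields of view are
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["NNResult", "nn_within", "nn_cross", "summarize_distances",
           "save_histogram"]


@dataclass
class NNResult:
    """Per-point nearest-neighbor assignments plus summary moments.

    ``pairs`` holds (point_id, neighbor_id, distance_nm); ``sd_nm`` uses the
    n-1 denominator and is 0 (with ``degenerate=True``) for a single
    distance.
    """

    pairs: list[tuple[int, int, float]]
    mean_nm: float
    sd_nm: float
    n: int
    degenerate: bool = False

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs])


def _summarize(pairs: list[tuple[int, int, float]]) -> NNResult:
    d = np.array([x[2] for x in pairs])
    degenerate = d.size == 1
    sd = 0.0 if degenerate else float(d.std(ddof=1))
    return NNResult(pairs=pairs, mean_nm=float(d.mean()), sd_nm=sd,
                    n=int(d.size), degenerate=degenerate)


def nn_within(centers, label: str = "") -> NNResult:
    """Distance from each point to its closest *other* point.

    Ties are broken toward the lowest neighbor index.  Fewer than two points
    cannot define a nearest neighbor and raise ``ValueError``.
    """
    pts = np.atleast_2d(np.asarray(centers, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError(
            f"nn_within needs >= 2 points{f' in channel {label!r}' if label else ''}, "
            f"got {pts.shape[0]}")
    dm = cdist(pts, pts)
    np.fill_diagonal(dm, np.inf)
    nbr = dm.argmin(axis=1)  # argmin takes the lowest index on ties
    pairs = [(i, int(j), float(dm[i, j])) for i, j in enumerate(nbr)]
    return _summarize(pairs)


def nn_cross(centers_a, centers_b, label: str = "") -> NNResult:
    """Distance from each point of A to the closest point of B (A→B).

    Asymmetric by construction; a zero distance is possible when
    coordinates coincide across channels.
    """
    a = np.atleast_2d(np.asarray(centers_a, dtype=float))
    b = np.atleast_2d(np.asarray(centers_b, dtype=float))
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError(
            f"nn_cross needs non-empty point sets"
            f"{f' ({label})' if label else ''}: |A|={a.shape[0]}, |B|={b.shape[0]}")
    dm = cdist(a, b)
    nbr = dm.argmin(axis=1)
    pairs = [(i, int(j), float(dm[i, j])) for i, j in enumerate(nbr)]
    return _summarize(pairs)


def summarize_distances(result: NNResult, bin_width_nm: float = 20.0):
    """Histogram with fixed-origin bins starting at 0, plus (mean, sd, n).

    Returns
    -------
    (counts, edges), (mean_nm, sd_nm, n)
    """
    d = result.distances
    if d.size < 1:
        raise ValueError("no distances to summarize")
    n_bins = max(1, int(np.ceil((d.max() + 1e-9) / bin_width_nm)))
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts, _ = np.histogram(d, bins=edges)
    return (counts, edges), (result.mean_nm, result.sd_nm, result.n)


def save_histogram(distances_nm, path, bin_width_nm: float = 20.0,
                   title: str = "") -> None:
    """Write a fixed-origin distance histogram as a PNG figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = np.asarray(distances_nm, dtype=float)
    n_bins = max(1, int(np.ceil((d.max() + 1e-9) / bin_width_nm)))
    edges = np.arange(n_bins + 1) * bin_width_nm
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(d, bins=edges, edgecolor="black", linewidth=0.5)
    ax.set_xlabel("distance (nm)")
    ax.set_ylabel("count")
    label = f"mean {d.mean():.0f} ± {d.std(ddof=1) if d.size > 1 else 0:.0f} nm (SD), n={d.size}"
    ax.set_title(f"{title}\n{label}" if title else label, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
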