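"""Spatial clustering statistics on ROI point sets.

Four complementary views of nanoscale organization:

* Hopkins index — clustering *tendency*; 0.5 under complete spatial
  randomness (CSR), approaching 1 for strongly clustered patterns.
* Ripley's K / L / H — clustering *extent*; H(r) = L(r) - r is zero under
  CSR and peaks near the characteristic cluster radius.
* DBSCAN — explicit cluster segmentation; the per-cluster density
  (molecules per nm of cluster diameter) summarizes packing.
* Getis-style local statistic — per-point ratio of local to global density
  with a Monte-Carlo CSR threshold, yielding cluster diameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .geometry import Region
from .postprocess import _link_components  # single-linkage helper


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Hopkins index


@dataclass
class HopkinsResult:
    value: float
    m: int
    n_iterations: int
    per_iteration: np.ndarray

    def __post_init__(self) -> None:
        self.per_iteration = np.asarray(self.per_iteration, dtype=float)


def hopkins_index(
    points: np.ndarray,
    region: Region,
    m: int | None = None,
    n_iterations: int = 100,
    seed=0,
    subsample_n: int | None = None,
) -> HopkinsResult:
    """Hopkins clustering-tendency statistic (squared-distance 2-D form).

    Per iteration, m uniform test locations and m sampled data points are
    drawn; with u_i the nearest-data distance from test location i and w_i
    the nearest-*other*-data distance from sampled point i, the iteration
    value is sum(u_i^2) / (sum(u_i^2) + sum(w_i^2)).  The result is the mean
    over iterations: 0.5 under CSR, -> 1 for clustered data.

    ``subsample_n`` optionally restricts the analysis to a random subsample
    of the data (off by default).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    rng = _rng(seed)
    if subsample_n is not None and subsample_n < len(points):
        points = points[rng.choice(len(points), size=subsample_n, replace=False)]
    n = len(points)
    if m is None:
        m = max(1, min(n // 10, 100))
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < 2 * m:
        raise ValueError(f"need at least 2*m = {2 * m} points, got {n}")
    tree = cKDTree(points)
    vals = np.empty(n_iterations)
    for it in range(n_iterations):
        test = region.sample_uniform(m, rng)
        u, _ = tree.query(test)
        sample_idx = rng.choice(n, size=m, replace=False)
        # nearest *other* data point: first hit is the point itself
        dists, _ = tree.query(points[sample_idx], k=2)
        w = dists[:, 1]
        u2, w2 = np.sum(u**2), np.sum(w**2)
        vals[it] = u2 / (u2 + w2) if (u2 + w2) > 0 else 1.0
    return HopkinsResult(float(vals.mean()), m, n_iterations, vals)


# ---------------------------------------------------------------------------
# Ripley's K / L / H


@dataclass
class RipleyCurve:
    r: np.ndarray  # nm
    k: np.ndarray  # nm^2
    edge_correction: str

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.k = np.asarray(self.k, dtype=float)

    @property
    def l(self) -> np.ndarray:
        return np.sqrt(self.k / np.pi)

    @property
    def h(self) -> np.ndarray:
        return self.l - self.r

    @property
    def peak_height(self) -> float:
        return float(self.h.max())

    @property
    def peak_radius(self) -> float:
        return float(self.r[int(np.argmax(self.h))])


def _toroidal_pair_distances(xy: np.ndarray, region: Region) -> np.ndarray:
    """All unordered pair distances with wrapped (torus) metric."""
    n = len(xy)
    out = []
    chunk = max(1, int(2e6 / max(n, 1)))
    for start in range(0, n, chunk):
        block = xy[start : start + chunk]
        dx = np.abs(block[:, None, 0] - xy[None, :, 0])
        dy = np.abs(block[:, None, 1] - xy[None, :, 1])
        dx = np.minimum(dx, region.width - dx)
        dy = np.minimum(dy, region.height - dy)
        d = np.sqrt(dx**2 + dy**2)
        for i in range(len(block)):
            out.append(d[i, start + i + 1 :])
    return np.concatenate(out) if out else np.empty(0)


def _isotropic_weights(xy: np.ndarray, d: np.ndarray, i_idx: np.ndarray,
                       region: Region) -> np.ndarray:
    """Ripley isotropic edge-correction weights for a rectangular window.

    For each directed pair (i, j) at distance r, the weight is the inverse
    of the fraction of the circle of radius r centered at i that lies
    inside the rectangle (Goreaud-Pelissier construction; valid for
    r <= min(side)/2).
    """
    x = xy[i_idx, 0] - region.x0
    y = xy[i_idx, 1] - region.y0
    e = np.stack(
        [x, region.width - x, y, region.height - y], axis=0
    )  # left, right, bottom, top
    r = d
    with np.errstate(invalid="ignore"):
        alpha = np.where(e < r[None, :], 2.0 * np.arccos(np.minimum(e / r, 1.0)), 0.0)
    ext = alpha.sum(axis=0)
    # corners: (left,bottom) (left,top) (right,bottom) (right,top)
    for a, b in ((0, 2), (0, 3), (1, 2), (1, 3)):
        both = e[a] ** 2 + e[b] ** 2 < r**2
        if np.any(both):
            corr = (
                np.pi / 2.0
                - np.arcsin(np.minimum(e[a][both] / r[both], 1.0))
                - np.arcsin(np.minimum(e[b][both] / r[both], 1.0))
            )
            ext[both] -= corr
    inside = 1.0 - ext / (2.0 * np.pi)
    return 1.0 / np.maximum(inside, 1e-9)


def ripley_curve(
    points: np.ndarray,
    region: Region,
    r_max: float = 500.0,
    n_r: int = 50,
    edge_correction: str = "toroidal",
) -> RipleyCurve:
    """Ripley's K(r) with L, H and peak extraction.

    K(r) = (area / n^2) * sum_i sum_{j != i} w_ij 1[d_ij <= r].  Edge
    corrections: ``"toroidal"`` (wrapped distances, w = 1; exact for
    synthetic torus fields), ``"isotropic"`` (rectangular-window circle
    weights, for real data), or ``"none"``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    if r_max > min(region.width, region.height) / 2.0:
        raise ValueError("r_max must not exceed half the region's short side")
    r = np.linspace(0.0, r_max, n_r)
    if edge_correction == "toroidal":
        d = _toroidal_pair_distances(points, region)
        d = np.sort(d[d <= r_max])
        counts = 2.0 * np.searchsorted(d, r, side="right")
    elif edge_correction in ("isotropic", "none"):
        tree = cKDTree(points)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs):
            dd = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
            # directed pairs, weights depend on the reference point
            i_idx = np.concatenate([pairs[:, 0], pairs[:, 1]])
            d_dir = np.concatenate([dd, dd])
            if edge_correction == "isotropic":
                w = _isotropic_weights(points, d_dir, i_idx, region)
            else:
                w = np.ones(len(d_dir))
            order = np.argsort(d_dir)
            d_sorted = d_dir[order]
            w_cum = np.concatenate([[0.0], np.cumsum(w[order])])
            counts = w_cum[np.searchsorted(d_sorted, r, side="right")]
        else:
            counts = np.zeros_like(r)
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    k = region.area / n**2 * counts
    k[r == 0] = 0.0
    return RipleyCurve(r, k, edge_correction)


# ---------------------------------------------------------------------------
# cluster segmentations


@dataclass(frozen=True)
class DbscanParams:
    eps: float = 50.0
    min_pts: int = 10

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")


@dataclass
class ClusterSet:
    """Per-point labels (-1 = noise) with per-cluster size/diameter/density."""

    labels: np.ndarray
    sizes: np.ndarray  # per cluster, count
    diameters: np.ndarray  # per cluster, nm (max pairwise distance)
    densities: np.ndarray  # per cluster, count / nm (nan if diameter 0)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _diameter(xy: np.ndarray) -> float:
    if len(xy) < 2:
        return 0.0
    if len(xy) > 400:  # hull vertices suffice for the max pairwise distance
        from scipy.spatial import ConvexHull

        try:
            xy = xy[ConvexHull(xy).vertices]
        except Exception:  # degenerate (collinear) input
            pass
    return float(pdist(xy).max())


def _build_cluster_set(labels: np.ndarray, points: np.ndarray) -> ClusterSet:
    ids = np.unique(labels[labels >= 0])
    sizes, diams = [], []
    for cid in ids:
        xy = points[labels == cid]
        sizes.append(len(xy))
        diams.append(_diameter(xy))
    sizes = np.asarray(sizes, dtype=np.int64)
    diams = np.asarray(diams, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(diams > 0, sizes / diams, np.nan)
    # relabel contiguously in input order
    remap = {int(c): k for k, c in enumerate(ids)}
    labels = np.array([remap.get(int(l), -1) for l in labels], dtype=np.int64)
    return ClusterSet(labels, sizes, diams, dens)


def dbscan_clusters(points: np.ndarray, params: DbscanParams) -> ClusterSet:
    """Standard DBSCAN segmentation with per-cluster diameter and density.

    Core point: >= min_pts neighbors within eps *including itself*; clusters
    are the density-connected components; border points attach to a core's
    cluster; the rest is noise.  Cluster diameter is the max pairwise
    distance; density = size / diameter (the relative nanocluster density).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        return ClusterSet(np.empty(0, np.int64), np.empty(0, np.int64),
                          np.empty(0), np.empty(0))
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit(points).labels_
    return _build_cluster_set(labels, points)


def mean_cluster_density(cluster_set: ClusterSet) -> float:
    """Unweighted mean of per-cluster densities (the one-point-per-ROI
    summary); NaN if there are no clusters with positive diameter."""
    d = cluster_set.densities[np.isfinite(cluster_set.densities)]
    if len(d) == 0:
        return float("nan")
    return float(d.mean())


def mean_cluster_diameter(cluster_set: ClusterSet) -> float:
    """Unweighted mean of per-cluster diameters; NaN without clusters."""
    if cluster_set.n_clusters == 0:
        return float("nan")
    return float(cluster_set.diameters.mean())


def getis_clusters(
    points: np.ndarray,
    region: Region,
    d: float = 100.0,
    n_null: int = 100,
    seed=0,
) -> ClusterSet:
    """Getis-style local clustering with a Monte-Carlo CSR threshold.

    Each point's statistic G_i is its neighbor count within ``d`` (self
    excluded) over n - 1, normalized by the CSR expectation pi d^2 / area —
    the ratio of the local sum to the global sum of points.  Points whose
    G_i exceeds the 95th percentile of the pooled statistic from ``n_null``
    CSR simulations of the same size are flagged as clustered and linked at
    distance ``d`` into connected components, whose diameters are reported
    as in DBSCAN.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    if d <= 0:
        raise ValueError("d must be positive")
    rng = _rng(seed)
    expect = np.pi * d**2 / region.area

    def _g(xy: np.ndarray) -> np.ndarray:
        tree = cKDTree(xy)
        counts = tree.query_ball_point(xy, d, return_length=True) - 1
        return counts / (len(xy) - 1) / expect

    g_obs = _g(points)
    null = np.concatenate([_g(region.sample_uniform(n, rng)) for _ in range(n_null)])
    threshold = float(np.quantile(null, 0.95))
    flagged = g_obs > threshold

    labels = np.full(n, -1, dtype=np.int64)
    if flagged.any():
        sub = points[flagged]
        comp = _link_components(sub, d)
        labels[flagged] = comp
    return _build_cluster_set(labels, points)
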