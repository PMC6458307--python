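"""Coordinate-based colocalization (CBC) between two channels.

For every localization i of the reference species A, the radial
distribution of same-species neighbors is compared with the radial
distribution of the other species B inside a search radius r_max (80 nm by
default, the scale of receptor nanoclusters).  With bins r_k = k * r_max /
n_bins::

    D_AA,i(r_k) = N_AA,i(r_k) / N_AA,i(r_max) * r_max^2 / r_k^2
    D_AB,i(r_k) = N_AB,i(r_k) / N_AB,i(r_max) * r_max^2 / r_k^2

S_i is the Spearman rank correlation of the two vectors, E_i the distance
from i to its nearest B localization, and the colocalization value

    C_i = S_i * exp(-E_i / r_max)   in [-1, +1],

+1 for perfect colocalization, -1 for perfect exclusion.  Same-species
counts exclude the localization itself; cross-species counts exclude at
most one localization at exactly zero distance, which is treated as the
same emitter detected in both channels (for continuous coordinates this is
a measure-zero event, and it makes cbc(A, A) return +1 for every
localization, the documented perfectly-colocalized endpoint).  When either
*count* vector is constant across bins — no neighbors inside r_max at all,
or a search radius so large that every bin already holds the total — the
radial profile carries no information and the rank correlation would only
reflect the deterministic 1/r^2 normalization; such localizations get
C_i = 0 ("no colocalization information") and are flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

_HIST_EDGES = np.linspace(-1.0, 1.0, 21)  # width-0.1 bins over [-1, 1]


@dataclass(frozen=True)
class CBCParams:
    r_max: float = 80.0
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.n_bins < 3:
            raise ValueError("n_bins must be >= 3 for a meaningful rank correlation")


@dataclass
class CBCResult:
    c: np.ndarray  # per-localization colocalization value in [-1, 1]
    s: np.ndarray  # Spearman rank correlation (nan where degenerate)
    e: np.ndarray  # nearest cross-species distance, nm
    degenerate: np.ndarray  # bool mask: constant distribution vector
    params: CBCParams

    @property
    def median(self) -> float:
        return float(np.median(self.c))

    @property
    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, fractions) over [-1, 1] in width-0.1 bins."""
        counts, edges = np.histogram(self.c, bins=_HIST_EDGES)
        return edges, counts / max(len(self.c), 1)


def _spearman_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation with average ranks; nan for constant rows."""
    ra = np.apply_along_axis(rankdata, 1, a)
    rb = np.apply_along_axis(rankdata, 1, b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        s = num / den
    s[den == 0] = np.nan
    return s


def _cumulative_counts(
    points_from: np.ndarray,
    points_to: np.ndarray,
    radii: np.ndarray,
    exclude_self: bool,
    exclude_one_zero: bool,
) -> np.ndarray:
    """N_i(r_k): neighbor counts of points_to around each of points_from."""
    tree = cKDTree(points_to)
    r_max = radii[-1]
    neighbors = tree.query_ball_point(points_from, r_max)
    counts = np.zeros((len(points_from), len(radii)))
    for i, idx in enumerate(neighbors):
        if not idx:
            continue
        d = np.linalg.norm(points_to[np.asarray(idx)] - points_from[i], axis=1)
        d = np.sort(d)
        if exclude_self or exclude_one_zero:
            zero = np.searchsorted(d, 0.0, side="right")
            if zero > 0:
                d = d[1:]  # drop one zero-distance entry
        counts[i] = np.searchsorted(d, radii, side="right")
    return counts


def cbc_values(
    points_a: np.ndarray, points_b: np.ndarray, params: CBCParams | None = None
) -> CBCResult:
    """Per-localization CBC values for species A against species B.

    Call with the arguments swapped for the symmetric B-against-A result.
    """
    if params is None:
        params = CBCParams()
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both point sets must be nonempty")
    radii = params.r_max * np.arange(1, params.n_bins + 1) / params.n_bins
    n_aa = _cumulative_counts(a, a, radii, exclude_self=True, exclude_one_zero=False)
    n_ab = _cumulative_counts(a, b, radii, exclude_self=False, exclude_one_zero=True)
    scale = (params.r_max / radii) ** 2

    def _dist(n: np.ndarray) -> np.ndarray:
        tot = n[:, -1]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = n / tot[:, None] * scale[None, :]
        d[tot == 0] = 0.0
        return d

    d_aa = _dist(n_aa)
    d_ab = _dist(n_ab)
    s = _spearman_rows(d_aa, d_ab)
    # constant count vectors carry no radial information: the D vectors
    # would differ only by the deterministic 1/r^2 factor
    flat = (np.ptp(n_aa, axis=1) == 0) | (np.ptp(n_ab, axis=1) == 0)
    s[flat] = np.nan
    e, _ = cKDTree(b).query(a)
    degenerate = ~np.isfinite(s)
    c = np.where(degenerate, 0.0, s * np.exp(-e / params.r_max))
    return CBCResult(c=c, s=s, e=e, degenerate=degenerate, params=params)


def cbc_summary(result: CBCResult) -> dict:
    """Median, histogram fractions, and the two endpoint-bin fractions."""
    if len(result.c) == 0:
        raise ValueError("empty CBC result")
    edges, frac = result.histogram
    return {
        "median": result.median,
        "bin_edges": edges,
        "fractions": frac,
        "fraction_at_plus1": float(frac[-1]),
        "fraction_at_minus1": float(frac[0]),
    }
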