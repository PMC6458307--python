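"""Post-processing of raw localization tables.

Implements the standard dSTORM cleanup chain in its canonical order —

1. remove duplicates (intra-frame re-localizations of one molecule),
2. uncertainty filter (drop imprecise localizations, > 20 nm),
3. density filter (drop isolated localizations: >= 2 neighbors in 50 nm),
4. drift correction from fiducial beads,
5. merging of multi-frame blinks of one molecule (within 20 nm),

plus fiducial-based polynomial channel registration.  Steps 1-3 and 5 act
on non-fiducial rows only; fiducial rows pass through untouched so they
remain available for drift estimation and registration.

Every operation is a pure function of its inputs: same table + parameters
-> identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import io
from .transforms import PolynomialTransform

logger = logging.getLogger("smlmpipe")

# Fiducial beads are micrometres apart; localizations of one bead scatter by
# drift + noise, far below this linking radius.
_BEAD_LINK_RADIUS = 500.0


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the post-processing chain (defaults as commonly used).

    ``duplicate_radius`` is either the string ``"uncertainty"`` (per-pair
    radius = max of the two localization uncertainties) or a fixed radius
    in nm.
    """

    duplicate_radius: float | str = "uncertainty"
    max_uncertainty: float = 20.0
    density_radius: float = 50.0
    density_min_neighbors: int = 2
    merge_radius: float = 20.0
    merge_max_gap_frames: int = 0
    drift_smoothing_window: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.duplicate_radius, (int, float)) and self.duplicate_radius <= 0:
            raise ValueError("duplicate_radius must be positive")
        if self.max_uncertainty <= 0:
            raise ValueError("max_uncertainty must be positive")
        if self.density_radius <= 0 or self.merge_radius <= 0:
            raise ValueError("radii must be positive")
        if self.density_min_neighbors < 1:
            raise ValueError("density_min_neighbors must be >= 1")


@dataclass
class DriftEstimate:
    """Per-frame stage offsets recovered from fiducials, anchored at frame 0."""

    offsets: np.ndarray  # (n_frames, 2) nm
    smoothing_window: int
    n_fiducials: int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.offsets)


def _split_fiducials(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mask = table["is_fiducial"].to_numpy(dtype=bool)
    return table.loc[~mask], table.loc[mask]


def _log(step: str, n_in: int, n_out: int) -> None:
    logger.info("step=%s rows_in=%d rows_out=%d", step, n_in, n_out)


# ---------------------------------------------------------------------------
# channel registration


def fiducial_centroids(table: pd.DataFrame, channel: str | None = None) -> np.ndarray:
    """Per-bead centroids of fiducial localizations, shape (n_beads, 2).

    Beads are identified by single-linkage grouping of fiducial rows within
    a 500 nm radius (beads are micrometres apart).
    """
    fid = table.loc[table["is_fiducial"]]
    if channel is not None:
        fid = fid.loc[fid["channel"] == channel]
    if len(fid) == 0:
        return np.empty((0, 2))
    xy = fid[["x", "y"]].to_numpy(dtype=float)
    labels = _link_components(xy, _BEAD_LINK_RADIUS)
    return np.vstack(
        [xy[labels == lab].mean(axis=0) for lab in range(labels.max() + 1)]
    )


def _link_components(xy: np.ndarray, radius: float) -> np.ndarray:
    """Single-linkage connected components at the given radius."""
    n = len(xy)
    pairs = cKDTree(xy).query_pairs(radius, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def fit_registration(
    fiducials_moving, fiducials_fixed, degree: int = 1
) -> PolynomialTransform:
    """Fit the polynomial transform mapping the moving channel onto the fixed.

    Accepts localization tables (bead centroids are computed and matched to
    the nearest fixed centroid) or raw (n, 2) arrays of matched control
    points.
    """
    if isinstance(fiducials_moving, pd.DataFrame):
        moving = fiducial_centroids(fiducials_moving)
    else:
        moving = np.atleast_2d(np.asarray(fiducials_moving, dtype=float))
    if isinstance(fiducials_fixed, pd.DataFrame):
        fixed = fiducial_centroids(fiducials_fixed)
    else:
        fixed = np.atleast_2d(np.asarray(fiducials_fixed, dtype=float))
    if len(moving) and len(fixed):
        # match each moving centroid to its nearest fixed centroid
        _, idx = cKDTree(fixed).query(moving)
        fixed = fixed[idx]
    return PolynomialTransform.fit(moving, fixed, degree=degree)


def apply_registration(
    table: pd.DataFrame, transform: PolynomialTransform, channel: str
) -> pd.DataFrame:
    """Apply a fitted registration to the named channel's coordinates."""
    present = set(table["channel"].unique())
    if channel not in present:
        raise ValueError(f"channel {channel!r} not in table (has {sorted(present)})")
    out = table.copy()
    mask = (out["channel"] == channel).to_numpy()
    xy = out.loc[mask, ["x", "y"]].to_numpy(dtype=float)
    new = transform.apply(xy)
    out.loc[mask, "x"] = new[:, 0]
    out.loc[mask, "y"] = new[:, 1]
    return out


# ---------------------------------------------------------------------------
# step 1: duplicates


def remove_duplicates(table: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Collapse intra-frame duplicate localizations.

    Within each frame and channel, localizations closer than the duplicate
    radius (per-pair radius = max of the two uncertainties in
    ``"uncertainty"`` mode) are grouped transitively; each group is replaced
    by its member with the smallest uncertainty.
    """
    table = table.reset_index(drop=True)
    data, fid = _split_fiducials(table)
    if len(data) == 0:
        return table.copy()
    keep = np.ones(len(data), dtype=bool)
    positions = data[["x", "y"]].to_numpy(dtype=float)
    unc = data["uncertainty"].to_numpy(dtype=float)
    per_pair = params.duplicate_radius == "uncertainty"
    grouped = data.reset_index(drop=True).groupby(["frame", "channel"], sort=False)
    idx_all = np.arange(len(data))
    for _, sub in grouped:
        ii = sub.index.to_numpy()
        if len(ii) < 2:
            continue
        xy = positions[ii]
        u = unc[ii]
        r_query = float(u.max()) if per_pair else float(params.duplicate_radius)
        if r_query <= 0:
            continue
        pairs = cKDTree(xy).query_pairs(r_query, output_type="ndarray")
        if len(pairs) == 0:
            continue
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        radius = (
            np.maximum(u[pairs[:, 0]], u[pairs[:, 1]])
            if per_pair
            else float(params.duplicate_radius)
        )
        close = pairs[d < radius]
        if len(close) == 0:
            continue
        labels = _components_from_pairs(close, len(ii))
        for lab in np.unique(labels[close.ravel()]):
            members = ii[labels == lab]
            if len(members) < 2:
                continue
            best = members[np.lexsort((members, unc[members]))[0]]
            keep[members] = False
            keep[best] = True
    kept = data.iloc[np.flatnonzero(keep)]
    result = pd.concat([kept, fid]).sort_index().reset_index(drop=True)
    _log("remove_duplicates", len(table), len(result))
    return result


def _components_from_pairs(pairs: np.ndarray, n: int) -> np.ndarray:
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


# ---------------------------------------------------------------------------
# step 2: uncertainty filter


def filter_uncertainty(table: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Drop localizations with uncertainty strictly above the threshold."""
    table = table.reset_index(drop=True)
    data, fid = _split_fiducials(table)
    kept = data.loc[data["uncertainty"] <= params.max_uncertainty]
    result = pd.concat([kept, fid]).sort_index().reset_index(drop=True)
    _log("filter_uncertainty", len(table), len(result))
    return result


# ---------------------------------------------------------------------------
# step 3: density filter


def density_filter(table: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Drop isolated localizations.

    A row is kept iff at least ``density_min_neighbors`` *other* rows of the
    same channel lie within ``density_radius`` (closed ball).  Neighbor
    counts are taken on the pre-filter set in a single pass; removals do not
    cascade.
    """
    table = table.reset_index(drop=True)
    data, fid = _split_fiducials(table)
    if len(data) == 0:
        return table.copy()
    keep = np.zeros(len(data), dtype=bool)
    positions = data[["x", "y"]].to_numpy(dtype=float)
    for _, sub in data.reset_index(drop=True).groupby("channel", sort=False):
        ii = sub.index.to_numpy()
        xy = positions[ii]
        tree = cKDTree(xy)
        counts = tree.query_ball_point(xy, params.density_radius, return_length=True)
        keep[ii] = (counts - 1) >= params.density_min_neighbors
    kept = data.iloc[np.flatnonzero(keep)]
    result = pd.concat([kept, fid]).sort_index().reset_index(drop=True)
    _log("density_filter", len(table), len(result))
    return result


# ---------------------------------------------------------------------------
# step 4: drift


def estimate_drift(
    table: pd.DataFrame, smoothing_window: int = 10
) -> DriftEstimate:
    """Estimate per-frame stage drift from fiducial beads.

    Each bead (grouped per channel by single linkage) contributes its
    per-frame displacement relative to its own mean position (mean removal
    rather than first-frame anchoring, so single-frame noise does not bias
    the whole path); the drift path is the mean over beads, moving-average
    smoothed (detrended first, so the centered window is unbiased at the
    edges for trending drift), linearly interpolated over frames without
    fiducial coverage, and anchored to (0, 0) at frame 0.
    """
    fid = table.loc[table["is_fiducial"]]
    if len(fid) == 0:
        raise ValueError(
            "no fiducial localizations; cross-correlation drift correction "
            "is not supported"
        )
    n_frames = int(table["frame"].max()) + 1
    series = []  # per-bead (frames, dxy)
    n_beads = 0
    for ch, sub in fid.groupby("channel", sort=False):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        frames = sub["frame"].to_numpy()
        labels = _link_components(xy, _BEAD_LINK_RADIUS)
        for lab in range(labels.max() + 1):
            m = labels == lab
            f, x = frames[m], xy[m]
            # average rows in the same frame, then reference = earliest frame
            df = pd.DataFrame({"f": f, "x": x[:, 0], "y": x[:, 1]})
            g = df.groupby("f").mean()
            disp = g[["x", "y"]].to_numpy()
            series.append((g.index.to_numpy(), disp - disp.mean(axis=0)))
            n_beads += 1
    # mean over beads, per frame
    acc = np.zeros((n_frames, 2))
    cnt = np.zeros(n_frames)
    for f, d in series:
        acc[f] += d
        cnt[f] += 1
    covered = cnt > 0
    mean_path = np.full((n_frames, 2), np.nan)
    mean_path[covered] = acc[covered] / cnt[covered, None]
    # interpolate uncovered frames
    idx = np.arange(n_frames)
    for ax in range(2):
        mean_path[:, ax] = np.interp(idx, idx[covered], mean_path[covered, ax])
    # Remove a linear trend before smoothing: a centered window with
    # truncated edges would otherwise bias the end frames of a drifting
    # path, and the anchoring below would propagate that bias everywhere.
    trend = np.column_stack(
        [np.polyval(np.polyfit(idx, mean_path[:, ax], 1), idx) for ax in range(2)]
    )
    resid = mean_path - trend
    if smoothing_window > 1:
        resid = (
            pd.DataFrame(resid)
            .rolling(smoothing_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    # Anchor frame 0 at (0, 0).  The trend value at frame 0 is estimated
    # from the whole series and is quiet; averaging the first few smoothed
    # residuals quiets the remaining local term.
    k = min(len(resid), max(2 * smoothing_window, 2))
    anchor = trend[0] + resid[:k].mean(axis=0)
    mean_path = trend + resid - anchor
    mean_path[0] = 0.0
    return DriftEstimate(mean_path, smoothing_window, n_beads)


def apply_drift_correction(table: pd.DataFrame, drift) -> pd.DataFrame:
    """Subtract each frame's drift offset from its rows' coordinates."""
    offsets = np.asarray(drift.offsets, dtype=float)
    frames = table["frame"].to_numpy()
    if len(table) and frames.max() >= len(offsets):
        raise ValueError(
            f"drift defined for {len(offsets)} frames but table has frame "
            f"{frames.max()}"
        )
    out = table.copy()
    if len(table):
        out["x"] = out["x"].to_numpy() - offsets[frames, 0]
        out["y"] = out["y"].to_numpy() - offsets[frames, 1]
    _log("drift_correction", len(table), len(out))
    return out


# ---------------------------------------------------------------------------
# step 5: merging


def merge_blinks(table: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Merge multi-frame re-appearances of one molecule into single records.

    Per channel, localizations in consecutive frames (gap up to
    ``merge_max_gap_frames``) within ``merge_radius`` of a chain's running
    uncertainty-weighted mean position are linked greedily in frame order
    (the running mean is a steadier anchor than the last blink alone).
    Each chain becomes one record at the 1/sigma^2-weighted mean position
    with combined uncertainty 1/sigma_c^2 = sum(1/sigma_i^2), carrying the
    chain's first frame and summed intensity.
    """
    data, fid = _split_fiducials(table)
    if len(data) == 0:
        return table.copy()
    merged_parts = []
    for ch, sub in data.groupby("channel", sort=False):
        merged_parts.append(_merge_channel(sub, params))
    result = pd.concat(merged_parts + [fid], ignore_index=True)
    result = result.sort_values(["frame", "x", "y"], kind="stable")
    result = io.reindex_ids(result)
    _log("merge_blinks", len(table), len(result))
    return result


def _merge_channel(sub: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    sub = sub.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    frames = sub["frame"].to_numpy()
    weights = 1.0 / np.maximum(sub["uncertainty"].to_numpy(dtype=float), 1e-6) ** 2
    chains: list[list[int]] = []
    open_chain_ids: list[int] = []
    open_pos: list[np.ndarray] = []  # running weighted mean per open chain
    open_w: list[float] = []
    open_last_frame: list[int] = []
    max_step = params.merge_max_gap_frames + 1

    for f in np.unique(frames):
        rows = np.flatnonzero(frames == f)
        # retire chains that can no longer be extended
        alive = [
            k for k in range(len(open_chain_ids)) if f - open_last_frame[k] <= max_step
        ]
        open_chain_ids = [open_chain_ids[k] for k in alive]
        open_pos = [open_pos[k] for k in alive]
        open_w = [open_w[k] for k in alive]
        open_last_frame = [open_last_frame[k] for k in alive]
        assigned = np.zeros(len(rows), dtype=bool)
        if open_chain_ids:
            eligible = [
                k
                for k in range(len(open_chain_ids))
                if open_last_frame[k] < f  # no two blinks of a chain per frame
            ]
            if eligible:
                cand = []  # (distance, row_index, chain_slot)
                tree = cKDTree(np.asarray([open_pos[k] for k in eligible]))
                for j, r in enumerate(rows):
                    hits = tree.query_ball_point(xy[r], params.merge_radius)
                    for h in hits:
                        k = eligible[h]
                        d = np.linalg.norm(xy[r] - open_pos[k])
                        cand.append((d, j, k))
                cand.sort()
                used_chain = set()
                for d, j, k in cand:
                    if assigned[j] or k in used_chain:
                        continue
                    assigned[j] = True
                    used_chain.add(k)
                    cid = open_chain_ids[k]
                    r = int(rows[j])
                    chains[cid].append(r)
                    w_new = open_w[k] + weights[r]
                    open_pos[k] = (open_pos[k] * open_w[k] + xy[r] * weights[r]) / w_new
                    open_w[k] = w_new
                    open_last_frame[k] = int(f)
        for j, r in enumerate(rows):
            if not assigned[j]:
                cid = len(chains)
                chains.append([int(r)])
                open_chain_ids.append(cid)
                open_pos.append(xy[r].copy())
                open_w.append(float(weights[r]))
                open_last_frame.append(int(f))
    # collapse chains
    recs = []
    unc = sub["uncertainty"].to_numpy(dtype=float)
    inten = sub["intensity"].to_numpy(dtype=float)
    mol = sub["molecule_id"]
    for members in chains:
        members = sorted(members)
        w = 1.0 / np.maximum(unc[members], 1e-6) ** 2
        pos = (xy[members] * w[:, None]).sum(axis=0) / w.sum()
        recs.append(
            {
                "id": 0,
                "frame": int(frames[members[0]]),
                "x": pos[0],
                "y": pos[1],
                "uncertainty": float(1.0 / np.sqrt(w.sum())),
                "intensity": float(inten[members].sum()),
                "channel": sub["channel"].iloc[0],
                "is_fiducial": False,
                "molecule_id": mol.iloc[members[0]],
            }
        )
    out = pd.DataFrame.from_records(recs)
    out["molecule_id"] = out["molecule_id"].astype("Int64")
    return out


# ---------------------------------------------------------------------------
# the full chain


def run_postprocess(
    table: pd.DataFrame,
    params: FilterParams | None = None,
    drift=None,
    transform: PolynomialTransform | None = None,
    registration_channel: str = "488",
) -> pd.DataFrame:
    """Run registration (optional) then the five-step chain in order.

    If ``drift`` is None and the table carries fiducials, drift is estimated
    from them; without fiducials the drift step is skipped (with a log
    note).  Per-step row counts are logged as ``step=<name> rows_in=<n>
    rows_out=<m>``.
    """
    if params is None:
        params = FilterParams()
    out = table
    if transform is not None:
        out = apply_registration(out, transform, registration_channel)
        _log("registration", len(table), len(out))
    out = remove_duplicates(out, params)
    out = filter_uncertainty(out, params)
    out = density_filter(out, params)
    if drift is None and bool(out["is_fiducial"].any()):
        drift = estimate_drift(out, smoothing_window=params.drift_smoothing_window)
    if drift is not None:
        out = apply_drift_correction(out, drift)
    else:
        logger.info("step=drift_correction skipped (no fiducials, no path given)")
    out = merge_blinks(out, params)
    return out
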