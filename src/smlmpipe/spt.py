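"""Single-particle tracking: linking, MSD, and diffusion estimation.

Detections are linked frame-to-frame by greedy mutual-nearest-neighbor
assignment (no gap closing), the time-averaged mean squared displacement
(MSD) is computed per trajectory, and the 2-D diffusion coefficient is the
slope/4 of an ordinary least-squares line through the first few MSD lags
with a free intercept (the intercept absorbs static localization error).
Default frame interval dt = 0.05 s (20 frames/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

D_FLOOR = 1e-6  # um^2/s; assigned when the MSD slope comes out negative


@dataclass
class Trajectory:
    """Ordered (frame, x, y) observations of one particle; x, y in nm."""

    frames: np.ndarray
    xy: np.ndarray
    dt: float = 0.05  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 observations")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DiffusionEstimate:
    D: float  # um^2/s
    msd_curve: np.ndarray  # um^2, index = lag (starting at lag 1)
    n_points_fit: int
    intercept: float  # um^2
    flagged: bool = False  # True when the slope was negative and floored


def link_tracks(
    detections: pd.DataFrame,
    max_disp: float,
    min_length: int = 10,
    dt: float = 0.05,
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Frame-to-frame greedy mutual-nearest-neighbor assignment within
    ``max_disp`` nm; unmatched detections start new tracks; a track that
    misses a frame ends (no gap closing).  Tracks shorter than
    ``min_length`` observations are discarded.

    ``detections`` is a localization-table-like DataFrame with at least
    ``frame``, ``x`` and ``y`` columns.
    """
    if len(detections) == 0:
        return []
    frames = np.sort(detections["frame"].unique())
    open_tracks: list[dict] = []  # {"frames": [...], "xy": [...]}
    done: list[dict] = []
    prev_frame = None
    for f in frames:
        sub = detections.loc[detections["frame"] == f, ["x", "y"]].to_numpy(float)
        if prev_frame is None or f != prev_frame + 1 or not open_tracks:
            done.extend(open_tracks)
            open_tracks = [{"frames": [int(f)], "xy": [p]} for p in sub]
            prev_frame = int(f)
            continue
        heads = np.asarray([t["xy"][-1] for t in open_tracks])
        # mutual nearest neighbors within max_disp
        tree_h = cKDTree(heads)
        tree_s = cKDTree(sub)
        d_hs, nn_of_head = tree_s.query(heads)  # head -> nearest detection
        d_sh, nn_of_det = tree_h.query(sub)  # detection -> nearest head
        matched_det = np.full(len(sub), -1, dtype=int)
        survivors = []
        for k, t in enumerate(open_tracks):
            j = nn_of_head[k]
            if d_hs[k] <= max_disp and nn_of_det[j] == k and matched_det[j] == -1:
                matched_det[j] = k
                t["frames"].append(int(f))
                t["xy"].append(sub[j])
                survivors.append(t)
            else:
                done.append(t)
        for j in range(len(sub)):
            if matched_det[j] == -1:
                survivors.append({"frames": [int(f)], "xy": [sub[j]]})
        open_tracks = survivors
        prev_frame = int(f)
    done.extend(open_tracks)
    return [
        Trajectory(np.asarray(t["frames"]), np.asarray(t["xy"]), dt=dt)
        for t in done
        if len(t["frames"]) >= max(min_length, 2)
    ]


def compute_msd(traj: Trajectory) -> np.ndarray:
    """Time-averaged MSD over overlapping pairs, lags 1..len//2, in um^2."""
    n = len(traj)
    xy_um = traj.xy / 1000.0
    max_lag = n // 2
    msd = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = xy_um[lag:] - xy_um[:-lag]
        msd[lag - 1] = np.mean(np.sum(disp**2, axis=1))
    return msd


def estimate_diffusion(
    traj: Trajectory, n_points_fit: int = 4
) -> DiffusionEstimate | None:
    """Per-track D from an OLS line through MSD lags 1..n_points_fit.

    D = slope / 4 for 2-D diffusion; the free intercept absorbs the
    localization-error offset (~ 4 sigma_loc^2).  Negative slopes are
    floored at 1e-6 um^2/s and flagged.  Returns None (a skip signal) when
    the track is too short to provide n_points_fit MSD lags.
    """
    msd = compute_msd(traj)
    if len(msd) < n_points_fit:
        return None
    lags_s = traj.dt * np.arange(1, n_points_fit + 1)
    slope, intercept = np.polyfit(lags_s, msd[:n_points_fit], 1)
    flagged = slope < 0
    d = max(slope / 4.0, D_FLOOR)
    return DiffusionEstimate(
        D=float(d),
        msd_curve=msd,
        n_points_fit=n_points_fit,
        intercept=float(intercept),
        flagged=bool(flagged),
    )


def population_summary(
    estimates: list[DiffusionEstimate], n_bins: int = 50
) -> tuple[float, pd.DataFrame]:
    """Median D and the empirical CDF over log-spaced D bins."""
    ds = np.asarray([e.D for e in estimates if e is not None], dtype=float)
    if len(ds) == 0:
        raise ValueError("no diffusion estimates")
    lo = max(ds.min(), D_FLOOR)
    hi = max(ds.max(), lo * 1.001)
    bins = np.logspace(np.log10(lo), np.log10(hi), n_bins)
    cdf = np.searchsorted(np.sort(ds), bins, side="right") / len(ds)
    curve = pd.DataFrame({"D_um2_per_s": bins, "cumulative_probability": cdf})
    return float(np.median(ds)), curve


def tracks_to_dataframe(tracks: list[Trajectory]) -> pd.DataFrame:
    """Flat (track_id, frame, x_nm, y_nm) table."""
    recs = []
    for tid, t in enumerate(tracks):
        for f, (x, y) in zip(t.frames, t.xy):
            recs.append((tid, int(f), float(x), float(y)))
    return pd.DataFrame(recs, columns=["track_id", "frame", "x_nm", "y_nm"])
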