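"""Synthetic two-color SMLM data with ground truth.

Emulates the features of membrane dSTORM data that the analysis pipeline
must handle: nanoclustered emitter fields (a Thomas-type cluster process on
a torus, plus uniform background), multi-blink re-localization across
frames with per-blink Gaussian error, stage drift, fiducial beads visible
in both channels, polynomial inter-channel misalignment, a tunable
cross-species coupling fraction (emulating ligand-induced association of
two receptor species), and 2-D Brownian trajectories for single-particle
tracking.

Every stochastic operation takes an explicit ``seed`` (an int or a
``numpy.random.Generator``); there is no hidden global RNG state, so all
outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .geometry import Region
from .transforms import ChannelWarp


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ClusterFieldParams:
    """Thomas-type cluster process parameters.

    ``n_clusters`` parent centers are placed uniformly; each receives a
    Poisson(``molecules_per_cluster_mean``) number of molecules offset by an
    isotropic Gaussian of scale ``cluster_sigma`` (nm).  A
    ``background_fraction`` share of the total molecules is uniform noise.
    """

    n_clusters: int = 30
    molecules_per_cluster_mean: float = 50.0
    cluster_sigma: float = 60.0
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.cluster_sigma <= 0:
            raise ValueError("cluster_sigma must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BlinkModel:
    """Photoswitching model: how often and how precisely a molecule appears.

    Each molecule blinks in k ~ Geometric(1/mean_blinks) distinct frames
    (support k >= 1); each blink's localization error and reported
    uncertainty are one draw from a log-normal with mean ``loc_sigma_mean``
    and standard deviation ``loc_sigma_spread`` (nm).
    """

    mean_blinks: float = 3.0
    loc_sigma_mean: float = 10.0
    loc_sigma_spread: float = 4.0
    n_frames: int = 1000

    def __post_init__(self) -> None:
        if self.mean_blinks < 1:
            raise ValueError("mean_blinks must be >= 1")
        if self.loc_sigma_mean < 0:
            raise ValueError("loc_sigma_mean must be >= 0 (0 = noiseless)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class DriftPath:
    """Per-frame stage offsets (dx, dy) in nm; frame 0 is the reference."""

    offsets: np.ndarray  # shape (n_frames, 2)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must have shape (n_frames, 2)")
        if len(self.offsets) and not np.allclose(self.offsets[0], 0.0):
            raise ValueError("frame-0 offset must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return len(self.offsets)

    def __neg__(self) -> "DriftPath":
        return DriftPath(-self.offsets)

    @classmethod
    def zero(cls, n_frames: int) -> "DriftPath":
        return cls(np.zeros((n_frames, 2)))

    @classmethod
    def linear(cls, n_frames: int, vx: float, vy: float) -> "DriftPath":
        """Constant-velocity drift of (vx, vy) nm per frame."""
        t = np.arange(n_frames)[:, None]
        return cls(t * np.array([vx, vy]))

    @classmethod
    def random_walk(cls, n_frames: int, step_sigma: float, seed) -> "DriftPath":
        rng = _rng(seed)
        steps = rng.normal(0.0, step_sigma, size=(n_frames, 2))
        steps[0] = 0.0
        return cls(np.cumsum(steps, axis=0))


@dataclass(frozen=True)
class BrownianParams:
    """Free 2-D diffusion at the paper-matched 20 frames/s (dt = 50 ms)."""

    D_true: float = 0.02  # um^2/s
    dt: float = 0.05  # s
    n_steps: int = 199
    loc_error_sigma: float = 20.0  # nm

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


# ---------------------------------------------------------------------------
# ground-truth emitter fields


@dataclass
class EmitterField:
    """Ground-truth molecule positions of one species.

    ``cluster_id`` is -1 for background molecules; ``coupled_to`` holds the
    molecule_id of the partner molecule in the other species, or -1.
    """

    region: Region
    species: str
    xy: np.ndarray  # (n, 2) nm
    molecule_id: np.ndarray  # (n,) int
    cluster_id: np.ndarray  # (n,) int, -1 = background
    coupled_to: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        n = len(self.xy)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.cluster_id = np.asarray(self.cluster_id, dtype=np.int64)
        if self.coupled_to is None:
            self.coupled_to = np.full(n, -1, dtype=np.int64)
        self.coupled_to = np.asarray(self.coupled_to, dtype=np.int64)
        if not (len(self.molecule_id) == len(self.cluster_id) == n):
            raise ValueError("field arrays must share one length")
        if len(np.unique(self.molecule_id)) != n:
            raise ValueError("molecule_ids must be unique within a species")

    @property
    def n(self) -> int:
        return len(self.xy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "molecule_id": self.molecule_id,
                "cluster_id": self.cluster_id,
                "x_nm": self.xy[:, 0],
                "y_nm": self.xy[:, 1],
                "coupled_to": self.coupled_to,
            }
        )


def write_truth(fields: list[EmitterField], path) -> None:
    """Write ground-truth fields as a flat CSV."""
    df = pd.concat([f.to_dataframe() for f in fields], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.2f", lineterminator="\n")


def generate_csr(region: Region, n: int, seed, species: str = "647") -> EmitterField:
    """Complete spatial randomness: n i.i.d. uniform molecules."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed)
    xy = region.sample_uniform(n, rng)
    return EmitterField(
        region,
        species,
        xy,
        molecule_id=np.arange(n),
        cluster_id=np.full(n, -1),
    )


def generate_cluster_field(
    region: Region, params: ClusterFieldParams, seed, species: str = "647"
) -> EmitterField:
    """Thomas-type clustered field plus uniform background.

    Cluster offsets are wrapped onto the region torus, which keeps the
    process stationary so the toroidally corrected Ripley K matches the
    Thomas closed form exactly in expectation.
    """
    rng = _rng(seed)
    counts = rng.poisson(params.molecules_per_cluster_mean, size=params.n_clusters)
    n_clustered = int(counts.sum())
    bg = params.background_fraction
    if bg >= 1.0:
        return generate_csr(region, n_clustered, rng, species=species)

    centers = region.sample_uniform(params.n_clusters, rng)
    offsets = rng.normal(0.0, params.cluster_sigma, size=(n_clustered, 2))
    xy = region.wrap(np.repeat(centers, counts, axis=0) + offsets)
    cluster_id = np.repeat(np.arange(params.n_clusters), counts)

    n_bg = int(round(n_clustered * bg / (1.0 - bg)))
    if n_bg:
        xy = np.vstack([xy, region.sample_uniform(n_bg, rng)])
        cluster_id = np.concatenate([cluster_id, np.full(n_bg, -1)])
    n = len(xy)
    return EmitterField(region, species, xy, np.arange(n), cluster_id)


def thomas_k(r, params: ClusterFieldParams, region: Region) -> np.ndarray:
    """Closed-form Ripley K of the generated field.

    For a pure Thomas process, K(r) = pi r^2 + (1/kappa)(1 - exp(-r^2/(4 sigma^2)))
    with kappa the cluster intensity.  Superposing a uniform background that
    makes up fraction p of all molecules scales the excess term by (1-p)^2.
    """
    r = np.asarray(r, dtype=float)
    kappa = params.n_clusters / region.area
    p = params.background_fraction
    excess = (1.0 - np.exp(-(r**2) / (4.0 * params.cluster_sigma**2))) / kappa
    return np.pi * r**2 + (1.0 - p) ** 2 * excess


def couple_fields(
    field_a: EmitterField,
    field_b_params: ClusterFieldParams,
    coupling_fraction: float,
    coupling_jitter: float,
    seed,
    species: str = "488",
) -> EmitterField:
    """Generate a species-B field partially coupled to species A.

    A ``coupling_fraction`` share of the B molecules is placed at a randomly
    chosen (with replacement) A position plus isotropic Gaussian jitter; the
    remainder follows ``field_b_params`` independently.  ``coupled_to``
    records the partner A molecule_id.
    """
    if not 0.0 <= coupling_fraction <= 1.0:
        raise ValueError("coupling_fraction must lie in [0, 1]")
    if coupling_fraction > 0 and field_a.n == 0:
        raise ValueError("cannot couple to an empty species-A field")
    rng = _rng(seed)
    base = generate_cluster_field(field_a.region, field_b_params, rng, species=species)
    n_coupled = int(round(coupling_fraction * base.n))
    if n_coupled == 0:
        return base
    which = rng.choice(base.n, size=n_coupled, replace=False)
    partners = rng.integers(0, field_a.n, size=n_coupled)
    jitter = (
        rng.normal(0.0, coupling_jitter, size=(n_coupled, 2))
        if coupling_jitter > 0
        else 0.0
    )
    xy = base.xy.copy()
    xy[which] = field_a.region.wrap(field_a.xy[partners] + jitter)
    cluster_id = base.cluster_id.copy()
    cluster_id[which] = -1
    coupled_to = np.full(base.n, -1, dtype=np.int64)
    coupled_to[which] = field_a.molecule_id[partners]
    return EmitterField(
        field_a.region, species, xy, base.molecule_id, cluster_id, coupled_to
    )


# ---------------------------------------------------------------------------
# from molecules to localization tables


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd <= 0:
        return np.log(mean), 0.0
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def simulate_localizations(
    field: EmitterField, blink: BlinkModel, seed
) -> pd.DataFrame:
    """Turn ground-truth molecules into a blink-level localization table.

    Each molecule switches on once, at a uniformly random frame, and stays
    on for k ~ Geometric(1/mean_blinks) consecutive frames (capped at the
    end of the acquisition) — the on-event that duplicate removal and
    multi-frame merging are designed to collapse.  Each blink is displaced
    by Gaussian noise of a per-blink scale drawn from the log-normal
    uncertainty distribution, and that scale is reported in the table's
    ``uncertainty`` column.
    """
    rng = _rng(seed)
    if field.n == 0:
        return io.empty_table()
    k = rng.geometric(1.0 / blink.mean_blinks, size=field.n)
    k = np.minimum(k, blink.n_frames)
    start = rng.integers(0, blink.n_frames, size=field.n)
    k = np.minimum(k, blink.n_frames - start)
    total = int(k.sum())
    frames = np.empty(total, dtype=np.int64)
    pos = 0
    for s0, ki in zip(start, k):
        frames[pos : pos + ki] = np.arange(s0, s0 + ki)
        pos += ki
    mol_idx = np.repeat(np.arange(field.n), k)
    if blink.loc_sigma_mean == 0:
        sigma = np.zeros(total)
    else:
        mu, s = _lognormal_params(blink.loc_sigma_mean, blink.loc_sigma_spread)
        sigma = (
            np.exp(mu + s * rng.standard_normal(total))
            if s > 0
            else np.full(total, blink.loc_sigma_mean)
        )
    xy = field.xy[mol_idx] + rng.standard_normal((total, 2)) * sigma[:, None]
    intensity = np.exp(np.log(1000.0) + 0.5 * rng.standard_normal(total))
    table = io.make_table(
        x=xy[:, 0],
        y=xy[:, 1],
        frame=frames,
        uncertainty=sigma,
        intensity=intensity,
        channel=field.species,
        is_fiducial=False,
        molecule_id=field.molecule_id[mol_idx],
    )
    return table.sort_values(["frame", "id"], kind="stable").pipe(io.reindex_ids)


def apply_drift(table: pd.DataFrame, drift: DriftPath) -> pd.DataFrame:
    """Translate each row by its frame's drift offset (forward simulation)."""
    frames = table["frame"].to_numpy()
    if len(table) and frames.max() >= drift.n_frames:
        raise ValueError(
            f"drift path covers {drift.n_frames} frames but table has frame "
            f"{frames.max()}"
        )
    out = table.copy()
    if len(table):
        out["x"] = out["x"].to_numpy() + drift.offsets[frames, 0]
        out["y"] = out["y"].to_numpy() + drift.offsets[frames, 1]
    return out


def add_fiducials(
    table: pd.DataFrame,
    region: Region,
    n_fiducials: int,
    loc_sigma: float,
    seed,
    n_frames: int | None = None,
    channels: tuple[str, ...] = ("647", "488"),
    min_separation: float = 1000.0,
) -> pd.DataFrame:
    """Append fiducial beads localized in every frame of every channel.

    Bead positions are uniform with a minimum pairwise separation
    (rejection sampling): well-separated beads are what makes them usable
    for drift estimation and registration.
    """
    if n_fiducials < 0:
        raise ValueError("n_fiducials must be >= 0")
    if n_fiducials == 0:
        return table.copy()
    if n_frames is None:
        if len(table) == 0:
            raise ValueError("n_frames required when the table is empty")
        n_frames = int(table["frame"].max()) + 1
    rng = _rng(seed)
    beads = np.empty((0, 2))
    for _ in range(1000 * n_fiducials):
        if len(beads) == n_fiducials:
            break
        cand = region.sample_uniform(1, rng)
        if len(beads) == 0 or np.min(
            np.linalg.norm(beads - cand, axis=1)
        ) >= min_separation:
            beads = np.vstack([beads, cand])
    else:
        raise RuntimeError("could not place fiducials at the requested separation")
    rows = []
    for ch in channels:
        for b in range(n_fiducials):
            noise = (
                rng.standard_normal((n_frames, 2)) * loc_sigma
                if loc_sigma > 0
                else np.zeros((n_frames, 2))
            )
            xy = beads[b] + noise
            rows.append(
                io.make_table(
                    x=xy[:, 0],
                    y=xy[:, 1],
                    frame=np.arange(n_frames),
                    uncertainty=max(loc_sigma, 1.0),
                    intensity=1e5,
                    channel=ch,
                    is_fiducial=True,
                )
            )
    return io.concat_tables(table, *rows)


def apply_channel_warp(
    table: pd.DataFrame, warp: ChannelWarp, channel: str
) -> pd.DataFrame:
    """Transform the named channel's coordinates by the polynomial warp."""
    present = set(table["channel"].unique())
    if channel not in present:
        raise ValueError(f"channel {channel!r} not in table (has {sorted(present)})")
    out = table.copy()
    mask = (out["channel"] == channel).to_numpy()
    xy = out.loc[mask, ["x", "y"]].to_numpy(dtype=float)
    warped = warp.apply(xy)
    out.loc[mask, "x"] = warped[:, 0]
    out.loc[mask, "y"] = warped[:, 1]
    return out


# ---------------------------------------------------------------------------
# Brownian trajectories for SPT


def simulate_brownian_tracks(params: BrownianParams, n_tracks: int, seed) -> list:
    """Simulate free 2-D Brownian trajectories with localization error.

    True increments per axis are N(0, 2 D dt); observed positions add
    independent Gaussian localization error.  Positions are in nm.
    """
    from .spt import Trajectory  # local import: spt does not import synthetic

    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = _rng(seed)
    step_nm = np.sqrt(2.0 * params.D_true * params.dt) * 1000.0
    tracks = []
    frames = np.arange(params.n_steps + 1)
    for _ in range(n_tracks):
        steps = rng.standard_normal((params.n_steps, 2)) * step_nm
        true = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        obs = true + rng.standard_normal(true.shape) * params.loc_error_sigma
        tracks.append(Trajectory(frames=frames.copy(), xy=obs, dt=params.dt))
    return tracks
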