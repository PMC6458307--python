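"""Scenario orchestration: simulate -> postprocess -> analyze -> report.

A scenario is one synthetic two-color acquisition plus its full analysis.
All parameters live in a flat :class:`PipelineConfig` that round-trips to a
YAML file, and every random draw descends from the single scenario seed, so
a config file alone regenerates every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats, colocalization, io, postprocess, spt, synthetic
from .geometry import Region
from .transforms import ChannelWarp

logger = logging.getLogger("smlmpipe")

CHANNEL_A = "647"  # fixed / reference channel
CHANNEL_B = "488"  # moving channel, mapped onto A by registration


@dataclass
class PipelineConfig:
    """Flat scenario configuration; defaults follow the standard protocol
    (20 nm uncertainty cut, 2 neighbors in 50 nm, 20 nm merge radius,
    3 x 3 um ROI, 80 nm CBC search radius, 20 frames/s SPT)."""

    scenario: str = "baseline"
    seed: int = 0
    # geometry
    region_size_nm: float = 4000.0
    roi_size_nm: float = 3000.0
    # species A emitter field (reference channel)
    a_n_clusters: int = 30
    a_molecules_per_cluster: float = 40.0
    a_cluster_sigma_nm: float = 60.0
    a_background_fraction: float = 0.1
    # species B emitter field + cross-species coupling
    b_n_clusters: int = 30
    b_molecules_per_cluster: float = 40.0
    b_cluster_sigma_nm: float = 60.0
    b_background_fraction: float = 0.1
    coupling_fraction: float = 0.1
    coupling_jitter_nm: float = 20.0
    # blinking / acquisition
    mean_blinks: float = 3.0
    loc_sigma_mean_nm: float = 10.0
    loc_sigma_spread_nm: float = 4.0
    n_frames: int = 500
    drift_step_sigma_nm: float = 0.3
    n_fiducials: int = 3
    fiducial_loc_sigma_nm: float = 2.0
    warp_dx_nm: float = 30.0
    warp_dy_nm: float = -10.0
    # post-processing
    max_uncertainty_nm: float = 20.0
    density_radius_nm: float = 50.0
    density_min_neighbors: int = 2
    merge_radius_nm: float = 20.0
    merge_max_gap_frames: int = 0
    drift_smoothing_window: int = 10
    registration_degree: int = 1
    # cluster statistics
    hopkins_m: int = 100
    hopkins_iterations: int = 100
    ripley_r_max_nm: float = 500.0
    ripley_n_r: int = 50
    dbscan_eps_nm: float = 50.0
    dbscan_min_pts: int = 10
    getis_distance_nm: float = 100.0
    # colocalization
    cbc_r_max_nm: float = 80.0
    cbc_n_bins: int = 10
    # single-particle tracking
    spt_D_um2_per_s: float = 0.02
    spt_dt_s: float = 0.05
    spt_n_steps: int = 199
    spt_loc_error_nm: float = 20.0
    spt_n_tracks: int = 200
    spt_max_disp_nm: float = 400.0
    spt_min_length: int = 10

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_params(self) -> postprocess.FilterParams:
        return postprocess.FilterParams(
            max_uncertainty=self.max_uncertainty_nm,
            density_radius=self.density_radius_nm,
            density_min_neighbors=self.density_min_neighbors,
            merge_radius=self.merge_radius_nm,
            merge_max_gap_frames=self.merge_max_gap_frames,
            drift_smoothing_window=self.drift_smoothing_window,
        )


def simulate_scenario(config: PipelineConfig):
    """Generate the raw two-color localization table and its ground truth.

    Returns (table, fields) where the table already carries blinking noise,
    stage drift, fiducials, and the inter-channel warp on channel B.
    """
    rng = np.random.default_rng(config.seed)
    region = Region(0.0, 0.0, config.region_size_nm, config.region_size_nm)
    params_a = synthetic.ClusterFieldParams(
        config.a_n_clusters,
        config.a_molecules_per_cluster,
        config.a_cluster_sigma_nm,
        config.a_background_fraction,
    )
    params_b = synthetic.ClusterFieldParams(
        config.b_n_clusters,
        config.b_molecules_per_cluster,
        config.b_cluster_sigma_nm,
        config.b_background_fraction,
    )
    field_a = synthetic.generate_cluster_field(region, params_a, rng, species=CHANNEL_A)
    field_b = synthetic.couple_fields(
        field_a,
        params_b,
        config.coupling_fraction,
        config.coupling_jitter_nm,
        rng,
        species=CHANNEL_B,
    )
    blink = synthetic.BlinkModel(
        config.mean_blinks,
        config.loc_sigma_mean_nm,
        config.loc_sigma_spread_nm,
        config.n_frames,
    )
    table = io.concat_tables(
        synthetic.simulate_localizations(field_a, blink, rng),
        synthetic.simulate_localizations(field_b, blink, rng),
    )
    table = synthetic.add_fiducials(
        table,
        region,
        config.n_fiducials,
        config.fiducial_loc_sigma_nm,
        rng,
        n_frames=config.n_frames,
        channels=(CHANNEL_A, CHANNEL_B),
    )
    drift = synthetic.DriftPath.random_walk(
        config.n_frames, config.drift_step_sigma_nm, rng
    )
    table = synthetic.apply_drift(table, drift)
    warp = ChannelWarp.translation(config.warp_dx_nm, config.warp_dy_nm)
    table = synthetic.apply_channel_warp(table, warp, CHANNEL_B)
    return table, [field_a, field_b]


def _channel_stats(points: np.ndarray, roi: Region, config: PipelineConfig,
                   rng: np.random.Generator) -> dict:
    n = len(points)
    m = min(config.hopkins_m, max(1, n // 2))
    hop = cluster_stats.hopkins_index(
        points, roi, m=m, n_iterations=config.hopkins_iterations, seed=rng
    )
    rip = cluster_stats.ripley_curve(
        points, roi, r_max=config.ripley_r_max_nm, n_r=config.ripley_n_r
    )
    dbs = cluster_stats.dbscan_clusters(
        points, cluster_stats.DbscanParams(config.dbscan_eps_nm, config.dbscan_min_pts)
    )
    get = cluster_stats.getis_clusters(
        points, roi, d=config.getis_distance_nm, seed=rng
    )
    return {
        "n_localizations": float(n),
        "hopkins": hop.value,
        "ripley_peak_height_nm": rip.peak_height,
        "ripley_peak_radius_nm": rip.peak_radius,
        "dbscan_n_clusters": float(dbs.n_clusters),
        "dbscan_mean_density_per_nm": cluster_stats.mean_cluster_density(dbs),
        "getis_mean_diameter_nm": cluster_stats.mean_cluster_diameter(get),
    }


def run_scenario(config: PipelineConfig, out_dir=None) -> dict:
    """Run one scenario end to end; returns the flat summary statistics.

    When ``out_dir`` is given, writes: the scenario config (YAML), raw and
    post-processed localization tables, ground truth, per-cluster tables,
    CBC per-localization values, SPT estimates, and ``summary.csv``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_file(out / "config.yaml")

    stage = "simulate"
    try:
        raw, fields = simulate_scenario(config)
        if out is not None:
            io.write_localizations(raw, out / "raw_localizations.csv")
            synthetic.write_truth(fields, out / "ground_truth.csv")

        stage = "postprocess"
        reg = postprocess.fit_registration(
            raw.loc[raw["is_fiducial"] & (raw["channel"] == CHANNEL_B)],
            raw.loc[raw["is_fiducial"] & (raw["channel"] == CHANNEL_A)],
            degree=config.registration_degree,
        )
        clean = postprocess.run_postprocess(
            raw,
            config.filter_params(),
            transform=reg,
            registration_channel=CHANNEL_B,
        )
        clean = clean.loc[~clean["is_fiducial"]].reset_index(drop=True)
        if out is not None:
            io.write_localizations(clean, out / "localizations.csv")

        stage = "roi"
        roi_table, roi = io.select_center_roi(clean, roi_size=config.roi_size_nm)

        stage = "cluster"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        summary: dict[str, float] = {"registration_rms_nm": reg.rms_residual}
        points = {}
        for ch, tag in ((CHANNEL_A, "a"), (CHANNEL_B, "b")):
            pts = roi_table.loc[
                roi_table["channel"] == ch, ["x", "y"]
            ].to_numpy(float)
            points[tag] = pts
            for key, val in _channel_stats(pts, roi, config, rng).items():
                summary[f"{key}_{tag}"] = val

        stage = "cbc"
        cbc_params = colocalization.CBCParams(config.cbc_r_max_nm, config.cbc_n_bins)
        res_ab = colocalization.cbc_values(points["a"], points["b"], cbc_params)
        res_ba = colocalization.cbc_values(points["b"], points["a"], cbc_params)
        summary["cbc_median_a_vs_b"] = res_ab.median
        summary["cbc_median_b_vs_a"] = res_ba.median
        if out is not None:
            for tag, res, pts in (("a", res_ab, points["a"]), ("b", res_ba, points["b"])):
                pd.DataFrame(
                    {
                        "x_nm": pts[:, 0],
                        "y_nm": pts[:, 1],
                        "S": res.s,
                        "E_nm": res.e,
                        "C": res.c,
                    }
                ).to_csv(out / f"cbc_{tag}.csv", index=False,
                         float_format="%.4f", lineterminator="\n")

        stage = "spt"
        spt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        bparams = synthetic.BrownianParams(
            config.spt_D_um2_per_s,
            config.spt_dt_s,
            config.spt_n_steps,
            config.spt_loc_error_nm,
        )
        tracks = synthetic.simulate_brownian_tracks(
            bparams, config.spt_n_tracks, spt_rng
        )
        # spread the tracks over a wide field so linking is exercised
        offsets = spt_rng.uniform(0, 40_000.0, size=(len(tracks), 2))
        dets = []
        for t, off in zip(tracks, offsets):
            dets.append(
                pd.DataFrame(
                    {"frame": t.frames, "x": t.xy[:, 0] + off[0], "y": t.xy[:, 1] + off[1]}
                )
            )
        linked = spt.link_tracks(
            pd.concat(dets, ignore_index=True),
            max_disp=config.spt_max_disp_nm,
            min_length=config.spt_min_length,
            dt=config.spt_dt_s,
        )
        estimates = [
            e for t in linked if (e := spt.estimate_diffusion(t)) is not None
        ]
        median_d, cdf = spt.population_summary(estimates)
        summary["spt_n_tracks"] = float(len(linked))
        summary["spt_median_D_um2_per_s"] = median_d
        if out is not None:
            pd.DataFrame(
                {
                    "track_id": range(len(estimates)),
                    "D_um2_per_s": [e.D for e in estimates],
                    "n_frames": [len(e.msd_curve) * 2 for e in estimates],
                    "flagged": [int(e.flagged) for e in estimates],
                }
            ).to_csv(out / "spt_estimates.csv", index=False,
                     float_format="%.6g", lineterminator="\n")
            cdf.to_csv(out / "spt_cdf.csv", index=False,
                       float_format="%.6g", lineterminator="\n")
    except Exception:
        logger.error("scenario %r failed at stage %s", config.scenario, stage)
        raise

    if out is not None:
        write_summary(summary, out / "summary.csv")
    return summary


def write_summary(summary: dict, path) -> None:
    """Write the flat statistic table with stable formatting."""
    with open(path, "w") as fh:
        fh.write("statistic,value\n")
        for key in sorted(summary):
            fh.write(f"{key},{summary[key]:.6g}\n")


def read_summary(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["statistic"], df["value"].astype(float)))


def compare_conditions(report_a: dict, report_b: dict) -> pd.DataFrame:
    """Per-statistic difference (b - a) and ratio (b / a) of two reports."""
    keys_a, keys_b = set(report_a), set(report_b)
    if keys_a != keys_b:
        missing = sorted(keys_a ^ keys_b)
        raise ValueError(f"reports carry different statistics: {missing}")
    rows = []
    for key in sorted(keys_a):
        va, vb = float(report_a[key]), float(report_b[key])
        rows.append(
            {
                "statistic": key,
                "value_a": va,
                "value_b": vb,
                "difference": vb - va,
                "ratio": vb / va if va != 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
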