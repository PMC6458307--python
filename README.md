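# smlmpipe

Analysis pipeline for two-color single-molecule localization microscopy
(dSTORM) of membrane receptor nano-organization — the kind of experiment
that asks whether two receptor species (for example the B-cell receptor IgM
and its co-receptor CD22) form nanoclusters, how dense those clusters are,
and whether the two species associate with each other.

The pipeline starts from localization tables (one row per detected blink:
frame, x/y in nm, uncertainty, intensity, channel) and provides:

* **Post-processing** — the standard five-step cleanup chain: intra-frame
  duplicate removal, uncertainty filtering (> 20 nm dropped), density
  filtering (≥ 2 neighbors within 50 nm required), fiducial-based drift
  correction, and merging of multi-frame blinks (within 20 nm), plus
  polynomial channel registration fitted on fiducial beads.
* **Cluster statistics** on a 3 × 3 µm ROI — Hopkins index (0.5 under
  complete spatial randomness, → 1 for clustered patterns), Ripley's
  K/L/H with peak extraction (H(r) = √(K(r)/π) − r), DBSCAN segmentation
  with relative cluster density (molecules per nm of cluster diameter),
  and a Getis-style local statistic yielding cluster diameters.
* **Coordinate-based colocalization (CBC)** — each localization i of
  species A receives C_i = S_i · exp(−E_i/r_max) ∈ [−1, +1], where S_i is
  the Spearman correlation of the same-species and cross-species radial
  density profiles D_AA,i(r_k) = N_AA,i(r_k)/N_AA,i(r_max) · r_max²/r_k²
  within r_max = 80 nm, and E_i is the nearest cross-species distance.
  +1 means perfectly colocalized, −1 perfectly excluded.
* **Single-particle tracking** — mutual-nearest-neighbor track linking,
  time-averaged MSD, and per-track diffusion coefficients D = slope/4 from
  an OLS fit to the first four MSD lags (free intercept absorbs
  localization error) at 20 frames/s.
* **A synthetic two-color data generator with ground truth** — Thomas-type
  clustered emitter fields, blinking, localization noise, stage drift,
  fiducials, polynomial inter-channel warp, a tunable cross-species
  coupling fraction, and 2-D Brownian trajectories — so every stage is
  testable against known truth without any external data.

## Worked example

```python
from smlmpipe import pipeline

config = pipeline.PipelineConfig(scenario="demo", seed=1, coupling_fraction=0.5)
summary = pipeline.run_scenario(config, out_dir="demo_out")
for key in ("hopkins_a", "ripley_peak_radius_nm_a",
            "dbscan_mean_density_per_nm_a", "cbc_median_a_vs_b",
            "spt_median_D_um2_per_s"):
    print(f"{key}: {summary[key]:.4g}")
```

prints (exactly reproducible for seed 1):

```
hopkins_a: 0.9801
ripley_peak_radius_nm_a: 153.1
dbscan_mean_density_per_nm_a: 0.2418
cbc_median_a_vs_b: 0.08393
spt_median_D_um2_per_s: 0.01974
```

Reading: the reference channel is strongly clustered (Hopkins ≈ 1 versus
0.5 for a random pattern), the Ripley H peak puts the cluster radius near
150 nm, DBSCAN clusters hold ≈ 0.24 molecules per nm of diameter, the
cross-channel CBC median is modestly positive at 50% coupling, and the
simulated tracks return a median diffusion coefficient of ≈ 0.02 µm²/s,
matching the generator's ground truth.

The same run is available from the shell:

```bash
smlmpipe run --config scenario.yaml --seed 1 --out demo_out
smlmpipe compare demo_out/summary.csv other_out/summary.csv --out cmp.csv
```

Per-stage subcommands (`simulate`, `postprocess`, `cluster`, `cbc`, `spt`)
expose each pipeline stage on its own; results go to files, logs to stderr.

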