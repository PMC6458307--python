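# Methods

This note documents the statistical models behind `smlmpipe`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical conventions that matter when reproducing
results.

## The data model

The pipeline's unit of data is the localization table: one row per
detected blink with frame index, position (nm), localization uncertainty
(nm, the standard error of the fitted position), optional photon count,
channel label, a fiducial flag, and — for synthetic data — the
ground-truth molecule id. Camera-frame reconstruction (PSF fitting) is out
of scope; the pipeline begins where reconstruction software ends.

Coordinates are continuous nanometres with origin at the region corner and
y increasing upward; frames are 0-based. Analysis regions are half-open
rectangles [x0, x0+w) × [y0, y0+h), so tiled regions count each point
exactly once.

## Synthetic data generator

The generator produces the study conditions every downstream stage is
validated against.

* **Emitter fields.** Nanoclustered species follow a Thomas-type process:
  cluster centers uniform on the region, per-cluster molecule counts
  Poisson(µ), isotropic Gaussian offsets of scale σ. Offsets are wrapped
  onto the region torus, which keeps the process stationary so the
  toroidally corrected Ripley K matches the closed form
  K(r) = πr² + (1−p)²·(1/κ)·(1 − exp(−r²/4σ²)) exactly in expectation
  (κ = cluster intensity; p = background fraction of uniformly scattered
  molecules, which scales the excess term by (1−p)²). Defaults — 30
  clusters of mean 40–50 molecules at σ = 60 nm with 10% background in a
  3–4 µm field — were chosen so that the Ripley H peak lands in the
  150–175 nm cluster-radius range typical of receptor nanoclusters; they
  are plausible, not calibrated to any real cell.
* **Cross-species coupling.** A fraction f of species-B molecules is
  placed at a randomly drawn species-A position plus Gaussian jitter
  (default 20 nm, about the scale of a labelled antibody sandwich),
  emulating ligand-induced association of the two receptors; the rest of
  B follows its own cluster process. f = 0 gives independent channels,
  f = 1 with zero jitter makes B a with-replacement resample of A.
* **Blinking.** Each molecule switches on once at a uniformly random frame
  and stays on for k ~ Geometric(1/mean_blinks) consecutive frames — the
  on-event that duplicate removal and multi-frame merging are designed to
  collapse. Re-blinking (multiple separate on-events of one fluorophore)
  is deliberately not modelled: a gap-0 merge cannot repair it, and
  including it would conflate generator artifacts with pipeline errors.
  Per-blink localization error and the reported uncertainty are one draw
  from a log-normal (mean 10 nm, spread 4 nm by default; log-normal
  guarantees positivity and matches typical uncertainty distributions).
  A zero mean is accepted as the noiseless limit.
* **Drift, fiducials, channel warp.** Drift paths are per-frame offsets
  (zero, linear, or Gaussian random walk; frame 0 is the reference).
  Fiducial beads are localized in every frame of both channels with their
  own noise scale and are placed with ≥ 1 µm separation — overlapping
  beads are useless for registration and are avoided in real sample
  preparation as well. Inter-channel misalignment is a degree-1 or
  degree-2 polynomial map shared with the registration code, so
  warp-then-register round trips are exact up to noise.
* **SPT.** Free 2-D Brownian motion: per-axis increments N(0, 2·D·dt),
  observed positions add Gaussian localization error. Defaults D = 0.02
  µm²/s, dt = 50 ms (20 frames/s), 200-frame tracks, 20 nm error.

What the generator does *not* emulate: camera-frame images, 3-D positions,
photophysics beyond the single on-event, fluorophore re-activation,
overcounting from multiple labels per molecule, membrane topography, and
confined or anomalous diffusion. Tests passing on this generator therefore
demonstrate correctness of the pipeline's algorithms under its stated
model, not robustness to every artifact of real dSTORM data.

## Post-processing chain

Registration (if a transform is supplied) runs first, then the five steps
in their canonical order: duplicates → uncertainty filter → density filter
→ drift correction → merging. All steps are pure functions; per-step row
counts are logged. Fiducial rows pass through steps 1–3 and 5 untouched so
they stay available for drift estimation.

Conventions the literature leaves open, fixed here:

* **Duplicates (step 1).** Within each frame and channel, localizations
  closer than the duplicate radius are grouped transitively; the pair
  radius is max of the two uncertainties ("uncertainty" mode) or a fixed
  value. Each group keeps its smallest-uncertainty member — step 1 is
  removal, not averaging; averaging is reserved for merging.
* **Uncertainty filter (step 2).** Strictly greater than 20 nm is
  removed; the boundary value stays.
* **Density filter (step 3).** A localization is kept iff ≥ 2 *other*
  localizations (self excluded, closed ball) lie within 50 nm, computed in
  a single pass on the pre-filter set; removals do not cascade.
* **Drift (step 4).** Each bead (grouped per channel by single linkage at
  500 nm) contributes its per-frame displacement relative to its own mean
  position; the bead average is detrended with a global line, the residual
  smoothed with a centered 10-frame moving average, the trend re-added,
  missing frames linearly interpolated, and the path anchored to (0, 0) at
  frame 0 using the trend value plus the mean of the first smoothed
  residuals. The mean-removal/detrending choreography matters: anchoring
  each bead at its noisy first-frame position, or smoothing a trending
  path through a truncated edge window, injects a constant ~1 nm error
  into the whole path. With 2 beads at 2 nm noise over 500 frames the
  recovered path RMS error is ≈ 0.8 nm.
* **Merging (step 5).** Per channel, blinks in consecutive frames (gap
  configurable, default 0) within 20 nm of a chain's running
  uncertainty-weighted mean are linked greedily in frame order; the
  running mean is a steadier anchor than the last blink and roughly halves
  spurious chain breaks. Each chain becomes one record at the
  1/σ²-weighted mean with combined uncertainty 1/σ_c² = Σ1/σ_i², the
  chain's first frame, and summed intensity; Σ1/σ² is conserved.
* **Registration.** Bead centroids are matched moving→nearest-fixed and a
  least-squares polynomial (degree 1 default; degree 2 available) is
  fitted; collinear bead layouts raise a conditioning error. The RMS fit
  residual is reported and bounds the registration error.

The ROI is a 3 × 3 µm square centered on the centroid of the non-fiducial
localizations — "middle of the cell" made deterministic — with a manual
center override. When the data's extent fits inside the window it is
nudged minimally to avoid cutting boundary points, making selection
idempotent.

## Cluster statistics

* **Hopkins.** Squared-distance 2-D form: per iteration, m uniform test
  positions and m sampled data points; value = Σu²/(Σu² + Σw²) with u the
  test-to-data and w the data-to-other-data nearest distances; mean over
  100 iterations. Defaults m = min(n/10, 100). Mean 0.5 under CSR
  (verified to ±0.02 over 100 replicates at n = 2000), → 1 for clustered
  data. An optional subsample size restricts the analysis to a random
  subset.
* **Ripley.** K(r) = (area/n²)·ΣΣ w_ij·1[d ≤ r] on a 50-point grid to
  500 nm. Edge corrections: toroidal (default; exact for the synthetic
  torus fields), isotropic (Goreaud–Pélissier circle-fraction weights for
  a rectangular window, valid to half the short side; for real data), or
  none. H = √(K/π) − r; peak height and radius are the max and argmax of
  H over the grid.
* **DBSCAN.** Standard semantics (core point: ≥ min_pts within eps
  including itself), delegated to scikit-learn and checked in the tests
  against an exhaustive density-connectivity oracle. Defaults eps = 50 nm,
  min_pts = 10, chosen so uniform backgrounds at the simulated densities
  come out mostly as noise; both echoed in output. Cluster diameter is
  the max pairwise distance ("diameter" read literally); relative density
  = size/diameter; the ROI summary is the unweighted mean over clusters
  (NaN, not an exception, when there are none).
* **Getis-style local statistic.** G_i = (neighbors within d, self
  excluded)/(n−1), normalized by the CSR expectation πd²/area — a ratio
  of the local to the global point sum. Points above the 95th percentile
  of the pooled statistic from 100 CSR simulations of the same size are
  flagged (≈ 5% false-positive rate under CSR, verified ≤ 6%), linked at
  distance d into connected components, and summarized by mean component
  diameter.

## Coordinate-based colocalization

For localization i of species A, with bins r_k = k·r_max/10 up to
r_max = 80 nm (the nanocluster radius scale): D_AA,i(r_k) =
N_AA,i(r_k)/N_AA,i(r_max)·r_max²/r_k², analogously D_AB,i; S_i = Spearman
correlation (average ranks for ties) of the two vectors; E_i = nearest
cross-species distance; C_i = S_i·exp(−E_i/r_max) ∈ [−1, +1]. Summaries:
median and a 20-bin histogram over [−1, 1] with the two endpoint-bin
fractions.

Two conventions are worth spelling out:

* Same-species counts exclude the localization itself. Cross-species
  counts exclude at most one localization at *exactly* zero distance,
  treated as the same emitter detected in both channels. For continuous
  coordinates this is a measure-zero event; its purpose is the endpoint
  case: with identical coordinate lists the count vectors become
  identical and every localization receives exactly +1. Keeping the
  coincident copy would instead shift every cross count by one, which
  flips Spearman ranks wherever counts are small and breaks the +1
  endpoint.
* Degeneracy is assessed on the raw count vectors: if either is constant
  across bins (no neighbors within r_max, or a radius so large every bin
  holds the total), the radial profile carries no information — the
  normalized D vectors would differ only by the deterministic 1/r² factor
  and Spearman would report a spurious +1. Such localizations get C = 0
  and a degenerate flag. −1 remains reachable through genuinely
  anti-correlated gradients, not through absence of neighbors.

Both directions (A against B, B against A) are computed and reported,
since the reference species is a free choice.

## Single-particle tracking

Linking is greedy mutual-nearest-neighbor between consecutive frames
within a displacement gate, with no gap closing (a missed frame ends the
track); tracks shorter than 10 frames are discarded by default. On
synthetic fields with spacing ≫ √(4·D·dt) the mis-link rate is below 5%.
The time-averaged MSD uses overlapping pairs for lags 1..⌊length/2⌋. D is
slope/4 of an OLS line through MSD lags 1–4 with a free intercept: few
lags keep the estimate low-bias, and the intercept absorbs the static
localization-error offset (≈ 4σ_loc², so σ_loc need not be known).
Negative slopes are floored at 10⁻⁶ µm²/s and flagged. Population
summaries are the median D and an empirical CDF over log-spaced bins.
Median D recovers truths of 0.005–0.08 µm²/s within 10% at 1000 tracks.

## Orchestration and determinism

A scenario is one flat YAML config (all parameters, one seed); every
random draw descends from that seed through named seed sequences, so a
config file alone regenerates every output byte-for-byte. Summary tables
are written with fixed formatting to keep runs diff-stable. Comparison of
two scenario reports gives per-statistic differences and ratios only — no
hypothesis testing.

Problem sizes used by the test suite and the acceptance script (100
Hopkins replicates at n = 2000, 50 Ripley replicates, 1000 SPT tracks,
20-replicate direction sweeps) were chosen as the smallest sizes at which
the Monte-Carlo envelopes are decisively tighter than the effects under
test.

## Known limitations

* The Hopkins/Ripley edge behavior is exact only for the synthetic torus;
  for real rectangular ROIs use the isotropic correction and keep
  r_max ≤ half the ROI side.
* The density filter's single pass and the merge's greedy linking are
  order conventions; pathological inputs (long chains of equidistant
  blinks) can depend on them.
* The Getis threshold is Monte-Carlo calibrated per call; with few null
  simulations the flagged fraction fluctuates around its nominal 5%.
* SPT linking has no gap closing and no motion model; it is validated for
  sparse fields, not crowded ones.
* CBC medians depend on localization density through the degenerate-zero
  convention: sparse channels pull the median toward 0.
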