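# Methods

This note records the modelling assumptions, defaults and numerical
choices behind `bassgeo`, and what the synthetic validation does and does
not demonstrate about real tag data.

## State-space model

The hidden state is the pair (grid cell, behaviour) on a regular grid of
5.2 km cells (WGS84 cell centers, row-major from the southwest corner).
Two behaviours — resident and migratory — each carry a diffusivity
`D` in km²/day.  One time step is one calendar day; within-day movement is
absorbed into `D`.

**Transition.**  Behaviour switches first by a 2×2 row-stochastic matrix
`S`, then position spreads by an isotropic Gaussian with per-axis variance
`2·D·Δt` km² — the spreading rate of a Fokker–Planck diffusion with
coefficient `D` in two dimensions.  The discrete kernel integrates the
Gaussian over destination cells (difference of normal CDFs per axis, taken
as a separable product), truncated at 4 standard deviations; this
truncation realises the reading of diffusivity as governing the maximum
distance the fish can move in a day.  Land cells receive zero mass and
each source row is renormalised over its reachable sea cells, so coasts
act as reflecting boundaries.  `D = 0` is exactly the identity.  The
cell-integrated kernel's per-axis second moment exceeds `2·D·Δt` by about
`h²/12` (h = cell size), ~2% at `D = 50`; this is the resolution floor of
a grid method and is left uncorrected.

**Observation model.**  Each day's likelihood over cells is a product of
independent layers, renormalised to sum to 1:

- *Bathymetric mask.*  Cells with seabed depth shallower than the day's
  maximum recorded depth are excluded.  A base tolerance of 5 m absorbs
  the tidal range and sensor noise contained in a pressure-derived
  maximum; without it the fish's own cell can mask itself out at high
  tide.
- *Tidal matching.*  While the fish rests on the seabed, the pressure
  record carries the local tidal elevation.  Sliding 3-h windows of the
  1-min depth series are fitted with a sinusoid at the M2 period
  (12.42 h) by linear least squares; windows with fit RMSE ≤ 0.3 m are
  accepted as resting "waves" (overlapping windows are merged and
  refitted).  Fitted amplitude and phase are compared per cell with
  Gaussian widths σ_amp = 0.3 m and σ_phase = 2π·(30 min)/12.42 h
  ≈ 0.25 rad.  The phase residual is wrapped to [−π, π].
- *Temperature matching.*  Temperature samples are paired with their
  simultaneous depth, thinned to one per hour to limit double-counting of
  serially dependent within-day samples, and compared with the gridded
  temperature at that depth (SST for samples above 5 m; linear
  interpolation between depth levels below; samples deeper than a cell's
  seabed use the seabed temperature).  Gaussian width σ_T = 0.7 °C,
  representing field error plus sensor error.
- *Endpoint anchors.*  Gaussian bumps at the release position (sd 2 km,
  ≈ one cell), a fishery recovery position (sd 5 km) or a beached
  recovery (sd 200 km, reflecting unknown drift).

The Gaussian widths are not stated by the tidal/temperature matching
literature for this configuration; all are exposed in
`LikelihoodConfig`.  If a day's product is empty the layer ladder falls
back in stages — drop the tidal layer, double σ_T, relax the mask in 5 m
steps, finally a uniform sea surface — and the step taken is recorded in
the day's provenance.

**Inference.**  Scaled forward–backward filtering/smoothing over the
joint state, with per-day normalisation constants accumulated into the
log-likelihood (equivalent to log-space arithmetic; the smoother runs in
double precision).  The Viterbi decoder maximises the joint path
probability in log space over the same truncated kernels; ties resolve
deterministically in favour of the first-scanned offset (lower cell
index).  Daily "most probable positions" are the argmax cells of the
smoothed spatial marginals, with ties broken northernmost-then-westernmost
and flagged; uncertainty is summarised as the area of the smallest cell
set holding 95% of the day's posterior.

**Parameter estimation.**  `(log D_res, log D_mig, logit S₁₁, logit S₂₂)`
are optimised by Nelder–Mead on the forward log-likelihood (single
precision — per-day rescaling keeps the recursion conditioned and the
direct search needs only ~1e-3 accuracy), with deterministic multi-start
(default 3 starts; the validation scenarios use 2 starts and 80
evaluations per start, which profiling showed is where the likelihood
stops improving materially).  Labels are ordered afterwards so that
`D_res ≤ D_mig`; a `collapsed` diagnostic flags `D_mig < 2·D_res`, where
the switch parameters are not identifiable.

## Fate classification

Float-up is the first sample of the terminal run with depth ≤ 1 m lasting
until the series end for ≥ 24 h; archives ending at depth are fishery
recoveries.  Drift duration is the day count from float-up to the last
recorded day.  Classification criteria, in order:

1. *Predation*: a pre-float supra-35 °C temperature span (spans split at
   >1 h gaps; spans shorter than 30 min are discarded as sensor spikes)
   **and** a pre-float daily surface fraction above the baseline's 95th
   percentile.  Both conditions are required to avoid false positives
   from isolated spikes.  The span duration is the stomach time.
2. *Capture and discard*: the float-start day's temperature range exceeds
   the archive's own 99th-percentile daily range by ≥ 8 °C (air
   exposure).  The margin is a package choice; no published value exists.
3. *Premature detachment* otherwise, with seabed/surface fractions of the
   final pre-float week reported as z-scores against the baseline
   (|z| > 2 flagged atypical).

"Near the seabed" means within 20% of the **daily** maximum depth (the
quantity being a daily proportion; a deployment-maximum variant is
config-selectable), and "near the surface" within 5 m.  In water
shallower than ~6 m the two bands overlap and both fractions can be 1 —
a documented degeneracy of the definition, not an error.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not any real coastline or tide:

- *Environment*: a coast along one grid edge with depth increasing
  monotonically offshore (5→120 m default); a single M2 constituent with
  amplitude decaying offshore (3→0.5 m) and phase propagating alongshore
  (span 1.5π); SST with a sinusoidal annual cycle (amplitude 4 °C), a
  latitudinal gradient (−2.5 °C across the grid) and day-varying field
  noise (sd 0.15 °C); temperature-at-depth equal to SST minus a
  summer-weighted stratification (≤ 3 °C to 150 m), never increasing with
  depth.  Field noise varies **by day**: a frozen spatial noise field
  would make matching errors perfectly correlated across days, which
  biases resident-diffusivity estimates toward zero and is not how daily
  ocean-analysis products behave.
- *Tracks*: daily steps drawn from the same two-behaviour Gaussian model
  the estimator assumes (per-axis sd `sqrt(2·D)`), rejection-sampled onto
  sea cells, clamped to the grid.
- *Archives*: per day, dive cycles between ~5% and ~95% of the seabed
  depth plus ≥ 1 seabed-resting window (3.5 h each, ~35% of the day
  resting) in which depth = seabed + M2 elevation; sensor noise sd 0.1 m
  (depth) and 0.1 °C (temperature); depth at 1-min, temperature at 10-min
  sampling.
- *Events*: predation holds temperature at ~36.5 °C with shallow
  oscillations (1.5–8.5 m) for the stomach duration; capture imposes a
  +10 °C, 30-min air-exposure excursion; every beached fate ends with a
  float phase (depth ≤ 1 m) drifting as a surface random walk at
  15 km/day (drift dynamics are unspecified in the field; a random walk
  is the minimal choice) with temperature tracking the drifted cells'
  SST.

Because resting-window prevalence in wild bass is not quantified, it is a
free scenario parameter; the default (two 3.5-h windows per day) makes
tidal fits available on essentially every day, which is optimistic
relative to fish that rarely rest.

## Validation scenarios and problem sizes

- *Exactness*: smoother and Viterbi agree with exhaustive path
  enumeration (3×3 grid, 4 days, 25 random instances) to ~1e-12.
- *Diffusivity recovery*: 20 fish × 300 days on a 60×60 grid, truth
  `(5, 120)` km²/day with stay-probabilities 0.9; median multiplicative
  error ≈ 1.8 (D_res) and ≈ 1.4 (D_mig).  Both diffusivities are
  somewhat biased low: small-`D` movement is partly invisible below the
  5.2 km cell scale, and grid clamping truncates the largest migratory
  excursions.  The switch probabilities are recovered only loosely and
  are reported, not asserted.
- *Track recovery*: a scripted 180-day seasonal offshore migration on a
  60×60 grid; median daily mode-position error ≈ 1 cell with all layers,
  ≈ 20 cells for the prior-only control.
- *Fate*: 200 archives with separable event parameters; label accuracy
  100%, drift days exact, stomach durations within 0.1 day.

These sizes were chosen so the full validation runs in minutes on a
single CPU while keeping each scenario's statistics stable across seeds.

**What this does not show.**  The synthetic fields are smooth and
single-constituent; real tidal residuals, multi-constituent beats,
mesoscale temperature structure and bathymetry error will widen real
position posteriors and can bias diffusivities further.  Passing the
synthetic recovery criteria demonstrates the inference machinery is
correct and well-calibrated *under its own assumptions*, not that a real
bass track is accurate to one cell.

## Other conventions and limitations

- Calendar: UTC; "day" is a calendar day; quarters are calendar quarters
  (Q1 = January–March).
- Distances: great-circle, Earth radius 6371 km.  Grid geometry assumes a
  locally uniform 5.2 km spacing; meridian convergence across a regional
  grid is ignored.
- Strategy thresholds 50/200 km with exact boundary values assigned to
  the lower class; the liberty gate is > 182 days.  The published table
  itself contains one distance/label inconsistency and two short-liberty
  labelled rows; the agreement invariant therefore compares distance
  thresholds only and asserts exactly one exception.
- Quarterly kernel densities assume independent daily positions, which
  serially correlated tracks violate; they are a visualisation of space
  use, not a probability model.
- The Fig.-5-style rolling-mean smoother is plotting plumbing only and is
  not validated against any curve-fitting method.
- Spawning-candidate flags are a screen (position depth quartile,
  8.5–11 °C, > 0.25 m/s vertical speed in Q1–Q2), not a demonstration of
  spawning.
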