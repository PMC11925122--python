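# Methods notes

This note records the models behind `sozdensity`, the parameters that
matter, and the choices made where the design was genuinely open. It is the
companion to the API docstrings, not a results report: every number quoted
here is computed by the test suite or `scripts/acceptance.py`.

## Coordinate and data conventions

Coordinates are millimetres in a right-handed RAS frame (+x right,
+y anterior, +z superior), the convention of neuroimaging tooling. All
indices are 0-based; grid contacts are stored row-major. Recordings are
channels × samples in microvolts with an explicit sampling rate, seizure
onset sample, and pre-onset baseline window. Recordings are stored in HDF5
(`data`, `channel_labels`, attributes for rate/onset/baseline); electrode
tables as CSV; masks as PNG + JSON sidecar; meshes as PLY.

## Decimation (the core manipulation)

LD recordings are built from HD hardware purely by dropping contacts:
grids lose every other row and column (4 mm → 8 mm), depth probes every
other contact (5 mm → 10 mm). The parity anchor is index 0 (keep row 0,
column 0) and is configurable; with the anchor fixed, LD contact sets are
strict subsets of HD sets, which is what later makes heat dominance exact
rather than statistical. Strips, recorded at 10 mm on both systems in the
motivating setting, pass through unchanged unless explicitly decimated.

## Signal conditioning

Order is fixed: anti-alias low-pass + resample → notch → bad-channel
exclusion (the notch is designed at the final rate). Filters are
zero-phase so onset latency is preserved.

- Anti-alias: FIR (Kaiser β = 9) low-pass at 255 Hz applied forward-
  backward, then polyphase resampling to 512 Hz with a Kaiser β = 14
  window (passband ripple ~1e-6, so DC and in-band content pass
  unchanged). Onset and baseline indices rescale proportionally.
- Notch: zero-phase IIR (Q = 30) at 60 Hz and every harmonic below
  Nyquist (60/120/180/240 Hz at 512 Hz). A second application changes the
  RMS of a 1/f-like signal by < 1%; broadband white noise, which has
  substantial energy inside the notch skirts, does not satisfy that bound
  and is not a realistic input.
- Bad channels: flat (whole-record SD below 1e-6 µV) or baseline SD above
  10× the median across channels. The criterion is a configurable stand-in;
  the motivating study did not publish one.

## Seizure-intensity heatmaps

Line length uses a 1.0 s trailing window with 0.1 s hop (configurable; the
transform is causal, first frame at t = window). Z-scoring uses the
recording's pre-ictal baseline window; channels with zero baseline
variability are an error, since they should have been excluded upstream.

Projection assigns each anatomy target the **maximum** of
`z_e · exp(−d²/2σ²)` over contacts within a cutoff, with σ = 5 mm and
cutoff 15 mm (= 3σ) by default. Applying the drop-off *before* the max
keeps distance informative; an additive rule would scale with electrode
count and unblind the density condition. Negative z-scores are retained in
the numeric frames and clamped to 0 only for display; monotonicity of the
displayed heat under contact removal (hence HD ≥ LD everywhere) is exact
for the clamped values — an uncovered target scores 0, which can exceed a
negative raw maximum, so the raw values are not strictly monotone.

Blinded rendering draws heat and a time axis only; the returned layer
manifest lets callers verify no electrode glyphs or condition metadata were
drawn. Omni-planar slices are pixel grids on a plane containing a depth
probe's trajectory; the in-plane roll about the probe is not constrained by
the hardware, so it is fixed by a caller-supplied hint vector
(Gram–Schmidt), making the basis deterministic.

## Synthetic data: what it emulates and what it does not

The seizure generator produces referential recordings at 3052 Hz with
white noise (SD 20 µV) everywhere and, after onset, a sinusoid whose
amplitude decays exponentially with distance from a focus
(300 µV at the focus, decay constant 10 mm, 2 s linear ramp). The default
oscillation frequency is 80 Hz, in the low-voltage-fast-activity range that
dominates recorded onsets — and, practically, line length responds to the
product of amplitude and frequency, so a fast rhythm is what makes the
transform spatially informative. This is the simplest model under which
line-length heatmaps carry the geometry; it makes no attempt at realistic
ictal morphology (no spike trains, no spectral evolution, no propagation),
so passing tests demonstrate the machinery, not clinical performance.
Tests of the "nearest channel wins" property use a steeper decay (5 mm) so
the ranking is deterministic rather than merely likely; baseline windows of
20 s are used there because the z-score scale is estimated from
overlapping line-length frames and stabilises slowly.

Simulated scorers jitter the true SOZ boundary with smooth (low-order
Fourier) radial noise of SD `boundary_jitter_px` (default 2 px), then
rescale about the centroid so the polygon log-area equals
`log(true area) + 0.227·[HD] + scorer bias + seizure effect` — jitter
perturbs shape, not expected area, so the configured HD-vs-LD log-area
multiplier is recovered exactly in expectation. Scorer bias SD defaults to
0.1 on the log scale. Confidence is a base Likert level 4, shifted by
−0.873 for multifocal annotations, minus a small jitter penalty, plus
noise, clipped to 1–5. Jitter magnitude is a free parameter controlling
agreement, not an estimate of any real scorer population.

Crossover schedules are balanced blocked randomisations (exactly half the
seizures HD-first, uniform over arrangements). Score tables are drawn from
the *exact* mixed models the inference module fits, with configurable fixed
effects (defaults: density 0.227 on log area; multifocal −0.873 on
confidence; overlap 1.606 on log area) and variance components
(scorer/seizure intercept SDs 0.3/0.4 on log area, residual 0.3) — the
parameter-recovery harness. All generators are pure functions of
(config, seed).

## Inference

Mixed models are fit with statsmodels `MixedLM` using variance components
for crossed scorer and seizure random intercepts (modelled as uncorrelated),
REML estimation, and Wald z confidence intervals; degrees-of-freedom
corrections (Satterthwaite etc.) are out of scope. Non-convergence and
captured fit warnings are reported on the result object, never silently
retried. Confidence is modelled numerically; an ordinal re-fit is not
provided.

The kappa comparison uses pair × seizure × condition rows with random
intercepts for scorer pair and seizure — one defensible reading of
"adjusting for scorer and seizure" at the pair level; per-scorer mean
kappas can be substituted by the caller. A single-pair, single-seizure
table degenerates to a paired difference with a warning.

Two numerical caveats, verified in the tests: when true variance
components are zero the REML estimates stop *near* the boundary (the
solver cannot represent exactly zero), so fixed effects match OLS to ~5e-3
rather than machine precision; and near-boundary fits can emit benign
`sqrt` warnings from the covariance computation, which are captured into
the result's warning list.

Power utilities: `effective_sample_size(n, deff) = n/deff` (a design
effect of 3.0 turns 60 observations per arm into 20), and
`min_detectable_effect` solves the two-sample noncentral-t power equation
(statsmodels `TTestIndPower`), giving d ≈ 0.909 at n = 20/arm, 80% power,
α = 0.05 two-sided; a vectorised Monte-Carlo t-test simulation serves as
its independent oracle.

## Agreement

Rasterisation uses even-odd ray casting at pixel centres ((c+0.5, r+0.5),
origin top-left), rings OR-ed for multifocal annotations, out-of-bounds
vertices clipped, self-intersecting rings filled even-odd with a warning.
Kappa's denominator is the full raster (so padding a raster *changes*
kappa through the chance term — the tests assert this rather than assuming
invariance); masks must share a raster spec to be compared. Undefined kappa
(both masks empty or both full, chance agreement 1) is recorded as missing,
never coerced to 0. Clinical overlap is any-pixel intersection with the
clinically determined region. Default annotation raster 800×600; the
agreement simulations in the tests use smaller rasters (120×120) purely
for speed.

## Density simulation

Nested cubic lattices share the origin, so coarser lattices are exact
subsets of finer ones; spacings must be pairwise integer multiples
(default 1/5/10 mm). The estimated SOZ is the convex hull of contacts
inside the true sphere (volume 0 below 4 non-coplanar points); a
voxel-union estimator (one spacing-sized cell per positive contact) is
available for sensitivity. Default sweep: radii 8–40 mm in 2 mm steps,
sphere centred on a lattice node, lattice half-extent = max radius + max
spacing; off-node centres via a jitter option. Three consequences are
exact by construction and asserted over the sweep: the hull of interior
points never exceeds the sphere's volume; finer spacing never decreases
the estimate (hull monotonicity under supersets); and the denser condition
is always at least as close to the truth. The HD-vs-LD percent difference
is reported only where the LD estimate is nonzero, and its magnitude
depends strongly on lattice geometry and the estimator, so it is checked
qualitatively (positive, shrinking with radius), not as a fixed band.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script each run
in well under a minute of CPU: 120-row score tables (6 scorers × 10
seizures × 2 conditions), 200 replicates for parameter recovery, 20,000
replicates for the Monte-Carlo power check, 50 seeded seizures for the
dominance check, 250 simulated seizures for the log-area multiplier check,
and 10–26 s synthetic recordings. All are arguments, not constants.

## Known limitations

- The synthetic seizure is stationary post-onset: no propagation, so
  inter-channel latency structure is absent.
- Scorer simulation jitters a single closed contour; genuinely multifocal
  (multi-ring) annotations are supported in rasterisation but the jitter
  model perturbs one region at a time.
- The mixed models assume Gaussian outcomes; Likert confidence is treated
  numerically (adequate for recovery simulations, coarse for real 5-point
  data).
- EDF input/output is not provided; recordings use the package's HDF5
  container.
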