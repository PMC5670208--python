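# Methods

This note documents the models, numerical choices and limitations behind
each stage of the package, and what the synthetic-data generator does and
does not emulate.

## Spectral analysis of PET time-activity curves

The tissue impulse response is represented as a non-negative mixture of
decaying exponentials over a fixed grid of frequencies.  With input
function C_p(t) (kBq/ml), whole-blood activity C_b(t) and frame-averaged
tissue activity C_i, the model for frame i is

C_i = (1 − V_b) Σ_j α_j B_ij + V_b W_i,

where B_ij is the frame average of C_p ⊗ e^{−β_j t} and W_i the
frame-averaged whole blood.  Estimation details:

- **Frequency grid.** 100 log-spaced β in [0.00063, 0.1] s⁻¹ by default.
  The bounds are fixed by the physics of the acquisition — the slow bound
  10^−3.2 s⁻¹ sits just above the ¹¹C decay constant 0.0005663 s⁻¹
  (log₁₀ −3.25), since no tissue kinetic can decay more slowly than the
  isotope; 0.1 s⁻¹ comfortably exceeds vascular transit rates.  The grid
  density (100 points) is a resolution choice: recovery error from
  off-grid kinetics is below 0.5% at this density.
- **Basis computation.** The convolution of the piecewise-linear input
  with e^{−βt} is evaluated by an interval recursion that is exact for
  linear segments; the small-βh branch switches to a series expansion to
  avoid catastrophic cancellation (relative error < 1e-6 down to β = 1e-8).
  Frame averages use the cumulative trapezoid of the dense (≤ 1 s) grid.
- **Solver.** Weighted bounded-variable least squares
  (`scipy.optimize.lsq_linear`, method `bvls`, tol 1e-12) on rows scaled by
  √w_i, with α_j ≥ 0 and 0 ≤ V_b ≤ 1.  The substitution γ_j = (1 − V_b)α_j
  keeps the problem linear; α is recovered afterwards (with a 1e-6 floor on
  1 − V_b, flagged `vb_saturated` when V_b ≈ 1; the raw γ spectrum is kept
  on the results as `alpha_raw`).  The solution was verified against an
  exhaustive face-enumeration quadratic-programming oracle (agreement to
  1e-6 on random small instances).
- **Weights.** w_i = L_i / T_i (frame length / trues rate), proportional to
  reciprocal frame variance.  Zero-trues frames get weight 0 with a
  warning rather than an infinite variance.
- **V_b convention.** The (1 − V_b) factor is applied to the tissue term;
  whether the original software did so is unknowable from the outside, so
  both the V_b-corrected V_T (primary) and the uncorrected Σγ_j/β_j are
  reported.
- **Units.** V_T is reported in ml/g assuming tissue density 1 g/ml.
- **Regularisation.** `rank_shaping_filter` applies a Gaussian kernel
  (σ = 0.15 decades) over log₁₀β to the NNLS spectrum — a variance-control
  filter in the spirit of rank-shaping for slowly equilibrating tracers.
  It is off by default and `none` reproduces plain spectral analysis; V_T
  accuracy, not spectral shape, is the validated quantity.
- **Known behaviour.** The NNLS estimator has a small negative noise bias
  (≈ −3% at the realistic noise level used in tests); the median |V_T|
  error is non-decreasing in the noise scale.  Both are characterised in
  the acceptance tests rather than corrected.

## Input function

- The plasma/whole-blood ratio sigmoid is fitted to the six early discrete
  samples (3–30 min); the parent-fraction sigmoid to all eight (3–75 min).
  A 90-min sample, when present, contributes plasma/whole-blood values only.
- Sigmoid family: 4-parameter logistic a + (b − a)/(1 + (t/c)^d), fitted by
  bounded multi-start Levenberg–Marquardt (8 starts; c > 0; the (a,b,d) ↔
  (b,a,−d) symmetry is canonicalised to d > 0).  Constant data short-
  circuit to an exact constant model.
- The continuous plasma curve (0–15 min) is merged with whichever of the
  20/30/50/60/75-min discrete plasma points exist (missing ones are
  logged); interpolation between merged points is piecewise linear.  This
  linear bridge is the dominant reconstruction error: on a realistic
  convex metabolite tail it leaves a few percent local error between late
  samples, while the fitted sigmoids themselves are recovered essentially
  exactly on noise-free data.
- Delay: grid search (default ±30 s, 0.5 s steps) minimising the weighted
  spectral-fit residual of the whole-brain TAC, re-windowing a single dense
  convolution rather than re-convolving per shift.  Exactly on-grid
  kinetics are recovered to the grid step; off-grid clearance can
  contribute up to half a grid step of systematic bias.  A flat objective
  (spread < 0.1% of the mean residual) or a boundary optimum raises a
  warning.

## SCR scoring

The printed rule is applied literally: an event requires a rise of
≥ 0.01 µS relative to the 1-s pre-stimulus baseline mean whose first
rising sample falls 0.5–3 s after the stimulus; amplitude is onset-to-peak;
one event (the first qualifying rise) per stimulus.  Implementation
choices: a 0.25 s moving average locates rising runs, after which onset and
peak are refined on the raw trace (last pre-rise minimum, local maximum),
so latencies are exact to one sample on clean data and robust to sensor
noise; the 0.5–3 s window anchors the onset by default (`window_anchor`
can switch to the peak); baseline width and smoothing are configuration
keys.  Rise-time is emitted per event but enters no statistic.

## Behavioural statistics

Friedman χ² uses within-subject mid-ranks with the standard tie-correction
divisor; an exact mode enumerates all (k!)^n within-subject arrangements
for small problems and was checked against an independent brute-force
enumeration.  The KS normality check tests against a normal with the
sample's own mean and SD (asymptotic p), and refuses zero-variance
samples.  AUC uses raw ratings by default (baseline-subtracted AUC is an
option) — which of the two the original analysis used is not stated.  No
correction is applied across scales by default; a Bonferroni switch exists.

## BOLD effect statistic

- Gamma-variate kernels (t/t_p)^q e^{q(1−t/t_p)} with peaks at 4 s and 8 s,
  shape q = 6, unit-peak normalised, sampled at 0.1 s and convolved with
  the signed event train.
- The "constrained" element of the fit is a non-negativity constraint on
  the combined response at its peak; because both kernels are unit-peak
  this reduces to Σ weights ≥ 0, enforced by an exact one-constraint
  projection when the OLS solution violates it (switchable).
- SSQ ratio = model SS / residual SS of the de-meaned series; a numerically
  perfect fit is capped at 1e6 and flagged; constant series yield 0.
- Voxel inference permutes the time series by circular shifts (or block
  permutation), p = (1 + #{perm ≥ obs})/(n_perm + 1) — valid by
  construction.  This replaces the original wavelet-resampling permutation
  at desk scale; the calibration safeguard is the measured uniformity of
  null p-values.
- Group inference: within-subject difference maps, across-subject median,
  sign-flip permutation; the voxel threshold is the pooled (1 − p) quantile
  of null |median| maps and the cluster-mass threshold is calibrated from
  the null cluster masses so the expected false-positive cluster count per
  volume is < 1 — by construction the realised null rate sits just below
  one, matching the rule rather than a conservative margin.  Clusters use
  face connectivity; coordinates are voxel indices.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

- **Cohort.** 14 subjects; right-amygdala V_T truncated-normal with mean
  12.57, SD 3.27, range 7.51–17.75 ml/g (rejection sampling).  Outcomes are
  built from the exactly standardised truncated V_T score, so requested
  population correlations are exact: the anxiety effect uses a standardised
  lognormal residual (σ = 0.8; the simplest one-parameter right-skew,
  reflecting skewed drug responses), the SSQ effect a Gaussian residual.
  The outcome–outcome correlation defaults to the product of the two V_T
  correlations (conditional independence given V_T) and is checked for
  joint feasibility (PSD).  A consequence worth knowing: with the skewed
  residual, the small-sample Pearson r is biased upward (mean ≈ 0.57 at
  n = 14 for a population value of 0.5), so correlation-recovery claims
  are asserted on the Gaussian-residual outcome; this is a property of
  skewed data at n = 14, not of the estimator.
- **Blood.** Whole blood is a unit-peak gamma-variate bolus (peak 30 kBq/ml
  at 60 s, sharpness 3) plus a recirculation tail; plasma/blood ratio rises
  1.05 → 1.6 (c = 8 min), parent fraction falls 1.0 → 0.25 (c = 15 min) —
  magnitudes typical of a lipophilic ¹¹C ligand with moderate metabolism.
  Discrete samples at 3/5/10/15/20/30/50/75 min; noise off by default.
- **TACs.** Analytic one-/two-tissue convolution on a 1 s grid, vascular
  term V_b·C_b, frame-averaged; noise SD per frame is
  noise_scale·√(T_i/L_i), matching the reciprocal-variance weight model.
  The realistic noise level used in tests is noise_scale 0.2 (≈ 4–20%
  frame-level noise across the scan).  Trues rates follow the decaying
  whole-body activity proxy.
- **SCR.** Difference-of-exponentials transients (rise 0.75 s, decay 2 s),
  onset latency uniform in [0.5, 3] s, valence-dependent amplitudes with a
  floor, sinusoidal tonic drift, optional sensor noise, minimum ISI 4 s
  enforced.  The original task's stimulus arithmetic does not close, so
  stimulus count and ISI are free parameters.
- **Ratings.** Placebo rows are constant at baseline (zero variance of
  change); drug rows add effect × profile with profile (0, 1, 1, 0.35) over
  0/1/2/3 h, so the 1–2 h window-mean change equals the subject's latent
  effect exactly.  STAI-S is clipped to [20, 80] (clipping is negligible at
  the default effect scales).
- **BOLD runs** (pipeline): cluster voxels carry condition-dependent
  response amplitudes proportional to the subject's latent SSQ effect, in
  Gaussian noise.

What the generator does **not** emulate: scanner resolution and
partial-volume effects, detector dispersion/dead-time, head motion,
metabolite chemistry beyond a single parent fraction, physiological SCR
artefacts, spatial autocorrelation of fMRI noise, or anatomical
variability.  Passing tests therefore demonstrate the correctness and
calibration of the estimators under their own statistical assumptions,
not performance on real scanner data.

## Problem sizes

Default study-scale runs use the 35-frame/95-min schedule with a 100-point
β grid; the noise study uses 200 replicates per level; permutation
calibration uses 500 null voxels × 500 permutations and 20 null / 20
effect volumes of 20³ voxels with 200 sign-flip permutations; correlation
closure uses 1000 cohorts of n = 14.  These sizes give Monte-Carlo error
well inside the asserted tolerances while keeping a full run to about a
minute.

## Known limitations

- The rank-shaping filter is a spectral smoothing stand-in for the cited
  regularisation method, validated only through V_T recovery.
- V_T maps are produced by looping the regional fit; no voxelwise
  parallelism.
- The permutation scheme for single-voxel inference assumes approximately
  exchangeable (weakly autocorrelated) noise under circular shifts; heavy
  temporal autocorrelation would require the block scheme with a suitable
  block length.
- The delay estimate inherits up to half a grid step of bias from off-grid
  kinetics (documented above).
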