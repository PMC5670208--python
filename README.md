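# cb1pipe

Quantitative analysis chain for a multimodal pharmacological imaging study
of the brain's cannabinoid system: PET quantification of CB1 receptor
availability, electrodermal and symptom scoring of an acute THC challenge,
a permutation-based fMRI effect statistic, and the correlation stage that
relates receptor availability to drug effects.  A synthetic-data generator
reproduces the statistical structure of such a study (a 14-subject
drug/placebo crossover), so every stage is testable without access to
subject-level data.

## What it computes

**PET kinetics (spectral analysis).**  Regional CB1 availability is
quantified as the total volume of distribution V_T of the radioligand
[¹¹C]MePPEP, from a frame-averaged time-activity curve C(t) and a
metabolite-corrected arterial input function C_p(t).  The tissue response
is modelled as a non-negative sum of convolutions with decaying
exponentials on a fixed log-spaced frequency grid β_j ∈ [0.00063, 0.1] s⁻¹,

    C(t) = (1 − V_b) Σ_j α_j (C_p ⊗ e^{−β_j t})(t) + V_b C_b(t),

solved by weighted non-negative least squares with frame weights
w_i = L_i / T_i (frame length over true-coincidence rate, i.e. reciprocal
variance), a free fractional blood volume V_b, and an optional
rank-shaping-style smoothing of the coefficient spectrum.  Then

    V_T = Σ_j α_j / β_j,      IRF(60 min) = Σ_j α_j e^{−β_j·3600}.

The slow frequency boundary (10^−3.2 ≈ 0.00063 s⁻¹) sits just above the
¹¹C decay constant ln2/(20.4·60) = 0.0005663 s⁻¹ (log₁₀ = −3.25), the
slowest kinetic an ¹¹C tracer can express.

**Input function.**  Continuous whole-blood counts (0–15 min) are converted
to plasma via a 4-parameter logistic fit of the plasma/whole-blood ratio of
the early discrete samples, merged with the late discrete plasma samples
(20–75 min), multiplied by a second logistic fitted to the parent
(unmetabolised) fraction, and aligned to the brain by a grid-search delay
that minimises the whole-brain spectral-fit residual.

**SCR scoring.**  A skin-conductance fluctuation is scored when a rise of
at least 0.01 µS relative to the pre-stimulus baseline begins 0.5–3 s after
a stimulus; amplitude is onset-to-peak, at most one event per stimulus.

**Behavioural statistics.**  Trapezoidal AUC of symptom ratings at
0/1/2/3 h, Friedman χ² across conditions (asymptotic or exact permutation),
Kolmogorov–Smirnov normality of changes from baseline, and the 1–2 h window
mean used as the effect measure.

**BOLD effect (desk scale).**  Event trains convolved with two unit-peak
gamma-variate kernels (4 s and 8 s peaks); the SSQ ratio (model SS /
residual SS) of the weighted-sum fit per voxel; circular-shift/block
permutation p-values; group comparison via the across-subject median map
with sign-flip permutation and cluster-mass thresholding calibrated to
fewer than one expected false-positive cluster per volume.

**Association.**  Pearson correlations of right-amygdala V_T with the
drug-induced anxiety change and the amygdala SSQ effect (primary), plus
post-hoc specificity checks, reported with n and one-/two-sided p.

## Worked example

```python
import numpy as np
from cb1pipe import (BloodProfile, KineticParams, SpectralAnalysisModel,
                     build_basis, gen_tissue_tac, meppep_frame_schedule,
                     synthetic_trues_rate)

profile = BloodProfile()                      # analytic arterial ground truth
input_fn = profile.input_function()           # parent plasma activity, 0-95 min
whole_blood = profile.whole_blood_curve()
schedule = meppep_frame_schedule(
    synthetic_trues_rate(meppep_frame_schedule(), input_fn))

truth = KineticParams(model="one-tissue", K1=12.57 * 0.002, k2=0.002, vb=0.05)
tac = gen_tissue_tac(input_fn, truth, schedule, noise_scale=0.2, seed=7,
                     whole_blood=whole_blood)
basis = build_basis(input_fn, schedule, whole_blood=whole_blood)
print(SpectralAnalysisModel(tac, basis).fit().summary())
```

prints

```
Spectral analysis fit
========================================
frames             35
beta grid          [6.30e-04, 1.00e-01] s^-1, 100 points
VT (ml/g)          11.9138
VT (uncorrected)   11.9138
Vb                 0.0000
IRF @ 60 min (1/s) 2.363262e-05
components         7
weighted RSS       9.000669e-01
```

The simulated region has true V_T = 12.57 ml/g (K1/k2); at this realistic
frame-noise level the spectral estimate of 11.91 ml/g is a −5% single-scan
error, consistent with the method's known small negative noise bias; V_b
collapses to 0 here because the noise obscures the 5% vascular signal.
The full synthetic study (cohort → blood → kinetics → SCR → ratings →
BOLD → correlations, with a markdown report) runs with

```
cb1pipe pipeline run --seed 1 --out out/
```

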