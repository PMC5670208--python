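"""Synthetic data emulating a two-condition THC/placebo crossover PET-fMRI study.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes: arterial blood datasets with
sigmoidal plasma/blood-ratio and parent-fraction time courses; tissue
time-activity curves from one- or two-tissue compartment models with known
volume of distribution; stimulus-locked skin-conductance sessions with a
ground-truth event list; symptom rating tables with zero placebo variance
and right-skewed drug responses; and subject-level cohorts in which
receptor availability (VT) carries configurable correlations with the drug
effects on anxiety and on the amygdala BOLD response.

Cohort defaults mirror the study population: 14 subjects, right-amygdala
VT with mean 12.57 ml/g, SD 3.27 ml/g, truncated to the observed range
7.51-17.75 ml/g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frames import FrameSchedule, decay_constant
from .input_function import BloodDataset, InputFunction, TimeCurve, _logistic4
from .kinetics import TissueTAC, exp_conv, frame_average
from .scr import SCRTrace

__all__ = [
    "CohortSpec",
    "KineticParams",
    "BloodProfile",
    "SCRSessionParams",
    "gen_blood_dataset",
    "gen_tissue_tac",
    "gen_scr_session",
    "gen_symptom_table",
    "gen_cohort",
    "synthetic_trues_rate",
]


@dataclass(frozen=True)
class CohortSpec:
    """Population parameters of the synthetic crossover cohort.

    ``anxiety_effect_corr`` and ``ssq_effect_corr`` are the population
    Pearson correlations between right-amygdala VT and, respectively, the
    drug-induced anxiety change and the drug effect on the amygdala SSQ
    ratio.  ``anxiety_ssq_corr`` optionally fixes the outcome-outcome
    correlation (default: the product of the two VT correlations, i.e.
    conditional independence given VT).
    """

    n_subjects: int = 14
    vt_mean: float = 12.57           # ml/g
    vt_sd: float = 3.27              # ml/g
    vt_range: tuple = (7.51, 17.75)  # ml/g
    anxiety_effect_corr: float = 0.5
    ssq_effect_corr: float = 0.5
    anxiety_ssq_corr: float | None = None
    scr_ssq_corr: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if not (self.vt_sd > 0):
            raise ValueError("vt_sd must be positive")
        if not (self.vt_range[0] < self.vt_range[1]):
            raise ValueError("vt_range must be an increasing pair")
        for r in (self.anxiety_effect_corr, self.ssq_effect_corr, self.scr_ssq_corr):
            if not (-1.0 <= r <= 1.0):
                raise ValueError("correlations must lie in [-1, 1]")
        np.linalg.cholesky(self.correlation_matrix() + 1e-12 * np.eye(3))

    def correlation_matrix(self) -> np.ndarray:
        """Implied (VT, anxiety, SSQ) correlation matrix; must be PSD."""
        r1, r2 = self.anxiety_effect_corr, self.ssq_effect_corr
        r12 = self.anxiety_ssq_corr if self.anxiety_ssq_corr is not None else r1 * r2
        m = np.array([[1.0, r1, r2], [r1, 1.0, r12], [r2, r12, 1.0]])
        if np.min(np.linalg.eigvalsh(m)) < -1e-10:
            raise ValueError("requested correlation pair is not jointly feasible "
                             "(correlation matrix not positive semi-definite)")
        return m


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth compartment-model parameters for TAC generation.

    One-tissue: VT = K1/k2.  Two-tissue: VT = (K1/k2) * (1 + k3/k4).
    ``vb`` is the fractional blood volume mixed into the measured signal,
    ``delay`` the bolus arrival delay (seconds) applied to the input.
    """

    model: str = "one-tissue"
    K1: float = 0.1    # ml/g/min is conventional; here treated per-second
    k2: float = 0.025  # 1/s-scale rates; only ratios enter VT
    k3: float | None = None
    k4: float | None = None
    vb: float = 0.05
    delay: float = 0.0

    def __post_init__(self):
        if self.model not in ("one-tissue", "two-tissue"):
            raise ValueError("model must be 'one-tissue' or 'two-tissue'")
        rates = [self.K1, self.k2]
        if self.model == "two-tissue":
            if self.k3 is None or self.k4 is None:
                raise ValueError("two-tissue model requires k3 and k4")
            rates += [self.k3, self.k4]
        if any(not np.isfinite(r) or r <= 0 for r in rates):
            raise ValueError("rate constants must be positive and finite")
        if not (0.0 <= self.vb <= 1.0):
            raise ValueError("vb must lie in [0, 1]")

    @property
    def vt(self) -> float:
        """Analytic total volume of distribution."""
        vt = self.K1 / self.k2
        if self.model == "two-tissue":
            vt *= 1.0 + self.k3 / self.k4
        return vt

    def impulse_response_terms(self):
        """Impulse response as [(coefficient, rate), ...] of exponentials."""
        if self.model == "one-tissue":
            return [(self.K1, self.k2)]
        s = self.k2 + self.k3 + self.k4
        disc = np.sqrt(s * s - 4.0 * self.k2 * self.k4)
        th1, th2 = (s - disc) / 2.0, (s + disc) / 2.0
        c = self.K1 / (th2 - th1)
        return [(c * (self.k3 + self.k4 - th1), th1),
                (c * (th2 - self.k3 - self.k4), th2)]


@dataclass(frozen=True)
class BloodProfile:
    """Analytic ground truth for the arterial blood generator.

    Whole blood is a unit-peak gamma-variate bolus plus a recirculation
    tail; the plasma/whole-blood ratio and the parent fraction follow
    4-parameter logistic curves of time in minutes.
    """

    peak_amplitude: float = 30.0   # kBq/ml at the bolus peak
    peak_time_s: float = 60.0
    bolus_sharpness: float = 3.0
    recirc_fraction: float = 0.25
    recirc_rise_s: float = 120.0
    recirc_decay_s: float = 2400.0
    # plasma/whole-blood ratio sigmoid (minutes): rises from ~1.05 to ~1.6
    ratio_params: tuple = (1.6, 1.05, 8.0, 2.5)
    # parent-fraction sigmoid (minutes): falls from 1.0 toward ~0.25
    parent_params: tuple = (0.25, 1.0, 15.0, 2.0)

    def __post_init__(self):
        vals = (self.peak_amplitude, self.peak_time_s, self.bolus_sharpness,
                self.recirc_fraction, *self.ratio_params, *self.parent_params)
        if any(not np.isfinite(v) for v in vals):
            raise ValueError("blood profile parameters must be finite")
        if self.peak_amplitude < 0:
            raise ValueError("bolus amplitude must be non-negative")

    def whole_blood(self, t_s):
        t = np.maximum(np.asarray(t_s, dtype=float), 0.0)
        k, tp = self.bolus_sharpness, self.peak_time_s
        with np.errstate(divide="ignore", invalid="ignore"):
            bolus = np.where(t > 0, (t / tp) ** k * np.exp(k * (1.0 - t / tp)), 0.0)
        tail = (1.0 - np.exp(-t / self.recirc_rise_s)) * np.exp(-t / self.recirc_decay_s)
        return self.peak_amplitude * ((1.0 - self.recirc_fraction) * bolus
                                      + self.recirc_fraction * tail)

    def ratio(self, t_min):
        return _logistic4(t_min, *self.ratio_params)

    def parent_fraction(self, t_min):
        return np.clip(_logistic4(t_min, *self.parent_params), 0.0, 1.0)

    def parent_plasma(self, t_s):
        """Ground-truth metabolite-corrected plasma parent activity."""
        t = np.asarray(t_s, dtype=float)
        return self.whole_blood(t) * self.ratio(t / 60.0) * self.parent_fraction(t / 60.0)

    def input_function(self, t_end_s: float = 5700.0,
                       step_s: float = 1.0) -> InputFunction:
        t = np.arange(0.0, t_end_s + step_s, step_s)
        return InputFunction(t, self.parent_plasma(t))

    def whole_blood_curve(self, t_end_s: float = 5700.0,
                          step_s: float = 1.0) -> TimeCurve:
        t = np.arange(0.0, t_end_s + step_s, step_s)
        return TimeCurve(t, self.whole_blood(t))


DISCRETE_SAMPLE_MIN = (3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0, 75.0)


def gen_blood_dataset(profile: BloodProfile | None = None, seed: int = 0,
                      noise_cv: float = 0.0,
                      discrete_times_min=DISCRETE_SAMPLE_MIN) -> BloodDataset:
    """Continuous (0-15 min, 1 s) and discrete arterial blood measurements.

    Discrete samples are drawn at the protocol times (3, 5, 10, 15, 20, 30,
    50 and 75 min) with plasma, whole-blood and parent-fraction values
    consistent with the profile's generating sigmoids.  ``noise_cv`` adds
    multiplicative Gaussian noise of that coefficient of variation to all
    measured activities (0 = noise-free); generation is deterministic in
    ``seed``.
    """
    profile = profile or BloodProfile()
    rng = np.random.default_rng(seed)
    cont_t = np.arange(0.0, 900.0 + 1.0, 1.0)
    cont_wb = profile.whole_blood(cont_t)
    disc_t = np.asarray(discrete_times_min, dtype=float)
    disc_wb = profile.whole_blood(disc_t * 60.0)
    disc_pl = disc_wb * profile.ratio(disc_t)
    disc_pf = profile.parent_fraction(disc_t)
    if noise_cv > 0:
        cont_wb = np.maximum(cont_wb * (1 + noise_cv * rng.standard_normal(cont_wb.size)), 0)
        disc_wb = np.maximum(disc_wb * (1 + noise_cv * rng.standard_normal(disc_wb.size)), 0)
        disc_pl = np.maximum(disc_pl * (1 + noise_cv * rng.standard_normal(disc_pl.size)), 0)
        disc_pf = np.clip(disc_pf + 0.5 * noise_cv * rng.standard_normal(disc_pf.size), 0, 1)
    return BloodDataset(cont_t, cont_wb, disc_t, disc_pl, disc_wb, disc_pf)


def synthetic_trues_rate(schedule: FrameSchedule, input_function,
                         scale: float = 1000.0,
                         half_life_minutes: float = 20.4) -> np.ndarray:
    """Plausible true-coincidence rates: activity-driven with physical decay."""
    lam = decay_constant(half_life_minutes)
    t = np.arange(0.0, schedule.total_duration + 1.0, 1.0)
    proxy = np.asarray(input_function(t), dtype=float) * np.exp(-lam * t)
    rate = scale * frame_average(t, proxy, schedule)
    return np.maximum(rate, 1e-3 * scale)


def gen_tissue_tac(input_function, kinetic_params: KineticParams,
                   frame_schedule: FrameSchedule, noise_scale: float = 0.0,
                   seed: int = 0, whole_blood=None,
                   region: str = "synthetic") -> TissueTAC:
    """Frame-averaged tissue TAC from an analytic compartment convolution.

    The impulse response of the chosen compartment model is convolved with
    the (delay-shifted) input function on a dense 1 s grid; the vascular
    term adds ``vb`` times the whole-blood curve; zero-mean Gaussian noise
    with per-frame variance proportional to T_i / L_i (scanner weighting
    model) scaled by ``noise_scale`` is added to the frame averages.
    """
    if frame_schedule.n_frames == 0:
        raise ValueError("empty frame schedule")
    p = kinetic_params
    t = np.arange(0.0, frame_schedule.total_duration + 1.0, 1.0)
    inp = input_function.shifted(p.delay) if p.delay else input_function
    dense_in = np.asarray(inp(t), dtype=float)
    tissue = np.zeros_like(t)
    for coef, rate in p.impulse_response_terms():
        tissue += coef * exp_conv(t, dense_in, np.array([rate]))[:, 0]
    measured = (1.0 - p.vb) * tissue
    if p.vb > 0:
        if whole_blood is None:
            raise ValueError("vb > 0 requires a whole-blood curve")
        measured = measured + p.vb * np.asarray(whole_blood(t), dtype=float)
    tac = frame_average(t, measured, frame_schedule)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(frame_schedule.trues_rate
                                   / frame_schedule.frame_duration)
        tac = tac + sd * rng.standard_normal(tac.size)
    return TissueTAC(frame_schedule, tac, region=region)


@dataclass(frozen=True)
class SCRSessionParams:
    """Generator settings for a stimulus-locked electrodermal session."""

    sampling_rate: float = 32.0       # Hz
    response_prob: float = 0.6
    amp_mean: float = 0.08            # microsiemens, neutral stimuli
    fearful_amp_offset: float = 0.04  # added to the mean for fearful stimuli
    amp_cv: float = 0.3
    amp_floor: float = 0.02
    latency_range: tuple = (0.5, 3.0)
    rise_tau: float = 0.75            # s
    decay_tau: float = 2.0            # s
    tonic_level: float = 5.0          # microsiemens
    drift_amplitude: float = 0.3
    noise_sd: float = 0.0
    min_isi: float = 4.0
    tail_s: float = 15.0


def _scr_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    tp = np.maximum(t, 0.0)
    k = np.where(t >= 0, np.exp(-tp / decay) - np.exp(-tp / rise), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def gen_scr_session(stimulus_table: pd.DataFrame,
                    params: SCRSessionParams | None = None,
                    seed: int = 0):
    """Synthetic SCR trace plus the ground-truth event list.

    Each stimulus elicits, with probability ``response_prob``, a
    difference-of-exponentials transient whose onset latency is uniform in
    ``latency_range`` and whose amplitude (floored at ``amp_floor``) is
    larger on average for fearful than neutral stimuli.  A slow sinusoidal
    tonic drift and optional Gaussian sensor noise are superimposed.

    Returns
    -------
    (SCRTrace, DataFrame)
        The trace and the truth table with columns ``stimulus_index``,
        ``onset_latency``, ``amplitude``, ``valence``.
    """
    p = params or SCRSessionParams()
    rng = np.random.default_rng(seed)
    stim = stimulus_table.reset_index(drop=True)
    onsets = stim["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(np.sort(onsets)) < p.min_isi):
        raise ValueError(f"stimuli closer than the minimum ISI ({p.min_isi} s)")
    duration = float(onsets.max()) + p.tail_s
    n = int(round(duration * p.sampling_rate))
    t = np.arange(n) / p.sampling_rate
    trace = (p.tonic_level
             + p.drift_amplitude * np.sin(2 * np.pi * t / max(duration, 1.0)))
    if p.noise_sd > 0:
        trace = trace + p.noise_sd * rng.standard_normal(n)

    truth = []
    for idx, stim_row in stim.iterrows():
        if rng.random() >= p.response_prob:
            continue
        valence = stim_row.get("valence", "neutral")
        latency = rng.uniform(*p.latency_range)
        mean_amp = p.amp_mean + (p.fearful_amp_offset if valence == "fearful" else 0.0)
        amp = max(p.amp_floor, rng.normal(mean_amp, p.amp_cv * mean_amp))
        onset = float(stim_row["onset_s"]) + latency
        trace = trace + amp * _scr_kernel(t - onset, p.rise_tau, p.decay_tau)
        truth.append(dict(stimulus_index=int(idx), onset_latency=float(latency),
                          amplitude=float(amp), valence=valence))
    truth_df = pd.DataFrame(truth, columns=["stimulus_index", "onset_latency",
                                            "amplitude", "valence"])
    return SCRTrace(p.sampling_rate, trace), truth_df


def _standardized_lognormal(rng, size, sigma: float = 0.8) -> np.ndarray:
    """Right-skewed residual with mean 0 and SD 1."""
    m = np.exp(sigma ** 2 / 2.0)
    s = np.sqrt((np.exp(sigma ** 2) - 1.0) * np.exp(sigma ** 2))
    return (rng.lognormal(0.0, sigma, size) - m) / s


def _truncnorm_z(rng, spec: CohortSpec, size):
    """Truncated-normal VT draws and their exactly standardised scores."""
    a = (spec.vt_range[0] - spec.vt_mean) / spec.vt_sd
    b = (spec.vt_range[1] - spec.vt_mean) / spec.vt_sd
    # rejection sampling of the truncated normal
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.standard_normal(size)
        keep = draw[(draw >= a) & (draw <= b)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    vt = spec.vt_mean + spec.vt_sd * out
    mu, var = stats.truncnorm.stats(a, b, moments="mv")
    z = (out - mu) / np.sqrt(var)
    return vt, z


# Latent effect scales (units of the respective outcome measures)
ANXIETY_EFFECT_MEAN, ANXIETY_EFFECT_SD = 10.0, 6.0     # STAI-S points
SSQ_EFFECT_MEAN, SSQ_EFFECT_SD = 0.06, 0.05            # SSQ-ratio units
PSYCHOSIS_EFFECT_MEAN, PSYCHOSIS_EFFECT_SD = 4.0, 2.5  # PANSS-positive points


def gen_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Subject-level records with the requested VT-outcome correlations.

    VT is truncated-normal within ``vt_range``; the anxiety effect mixes
    the standardised VT score with an independent right-skewed residual so
    that its population Pearson correlation with VT is exactly
    ``anxiety_effect_corr``; the SSQ effect does the same with a Gaussian
    residual.  The fearful-face SCR count change is correlated with the
    SSQ effect at ``scr_ssq_corr``; the psychosis change is independent of
    VT (the specificity control).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    spec.correlation_matrix()  # feasibility check
    r1, r2 = spec.anxiety_effect_corr, spec.ssq_effect_corr
    r12 = spec.anxiety_ssq_corr if spec.anxiety_ssq_corr is not None else r1 * r2

    vt, z = _truncnorm_z(rng, spec, n)
    eps_anx = _standardized_lognormal(rng, n)
    eps_ssq = rng.standard_normal(n)
    x_anx = r1 * z + np.sqrt(max(0.0, 1.0 - r1 ** 2)) * eps_anx
    b = 0.0 if abs(r1) >= 1.0 else (r12 - r1 * r2) / np.sqrt(1.0 - r1 ** 2)
    c2 = 1.0 - r2 ** 2 - b ** 2
    x_ssq = r2 * z + b * eps_anx + np.sqrt(max(0.0, c2)) * eps_ssq

    r_scr = spec.scr_ssq_corr
    x_scr = r_scr * x_ssq + np.sqrt(max(0.0, 1 - r_scr ** 2)) * rng.standard_normal(n)
    psychosis = PSYCHOSIS_EFFECT_MEAN + PSYCHOSIS_EFFECT_SD * _standardized_lognormal(rng, n)

    return pd.DataFrame({
        "subject": [f"S{i + 1:02d}" for i in range(n)],
        "vt_right_amygdala": vt,
        "anxiety_delta": ANXIETY_EFFECT_MEAN + ANXIETY_EFFECT_SD * x_anx,
        "ssq_effect": SSQ_EFFECT_MEAN + SSQ_EFFECT_SD * x_ssq,
        "scr_fear_count_delta": np.rint(3.0 + 2.0 * x_scr).astype(int),
        "psychosis_delta": psychosis,
    })


# Rating-scale layout: baseline, (lower, upper) instrument bounds
RATING_SCALES = {
    "STAI-S": (32.0, (20.0, 80.0)),
    "AIS": (0.0, (0.0, 100.0)),
    "PANSS-pos": (7.0, (7.0, 49.0)),
    "PANSS-neg": (7.0, (7.0, 49.0)),
    "PANSS-total": (30.0, (30.0, 210.0)),
}
# Shape of the transient drug response over 0/1/2/3 h; the 1-2 h plateau
# makes the 1-2 h window-mean change equal the subject's latent effect.
TIME_PROFILE = {0.0: 0.0, 1.0: 1.0, 2.0: 1.0, 3.0: 0.35}


def gen_symptom_table(spec: CohortSpec, seed: int | None = None,
                      cohort: pd.DataFrame | None = None,
                      effect_scale: float = 1.0) -> pd.DataFrame:
    """Long-format ratings: subject x condition x scale x time (0/1/2/3 h).

    Placebo ratings are constant at each scale's baseline (zero variance of
    change); drug ratings add a right-skewed transient peaking over 1-2 h
    whose STAI-S magnitude is the cohort's ``anxiety_delta`` and whose
    PANSS-positive magnitude is ``psychosis_delta``.  Values are clipped to
    instrument bounds.
    """
    if cohort is None:
        cohort = gen_cohort(spec, seed=seed)
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    n = len(cohort)
    effects = {
        "STAI-S": cohort["anxiety_delta"].to_numpy(),
        "AIS": 40.0 + 15.0 * _standardized_lognormal(rng, n),
        "PANSS-pos": cohort["psychosis_delta"].to_numpy(),
        "PANSS-neg": 3.0 + 2.0 * _standardized_lognormal(rng, n),
    }
    effects["PANSS-total"] = effects["PANSS-pos"] + effects["PANSS-neg"]
    effects = {k: effect_scale * v for k, v in effects.items()}
    rows = []
    for i, subj in enumerate(cohort["subject"]):
        for scale, (baseline, bounds) in RATING_SCALES.items():
            for time_h, weight in TIME_PROFILE.items():
                rows.append((subj, "placebo", scale, time_h, baseline))
                value = float(np.clip(baseline + weight * effects[scale][i], *bounds))
                rows.append((subj, "drug", scale, time_h, value))
    return pd.DataFrame(rows, columns=["subject", "condition", "scale",
                                       "time_h", "value"])
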