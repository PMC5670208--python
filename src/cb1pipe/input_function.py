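"""Arterial input-function construction with metabolite and delay correction.

The driving term of PET kinetic models is the arterial plasma activity of
the unmetabolised (parent) radiotracer.  It is assembled from:

1. a continuous whole-blood curve measured by an on-line detector over the
   first 15 minutes of the scan;
2. intermittent discrete arterial samples, which provide plasma activity,
   whole-blood activity and the parent (unmetabolised) fraction at a handful
   of time points;
3. a 4-parameter sigmoid fitted to the plasma/whole-blood ratio of the early
   discrete samples, used to convert the continuous whole-blood curve to a
   continuous plasma curve;
4. a second 4-parameter sigmoid fitted to the measured parent fractions,
   used to correct the total plasma curve to parent-only activity;
5. a whole-brain delay term aligning bolus arrival at the peripheral
   sampling site with arrival at the brain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BloodDataset",
    "SigmoidModel",
    "TimeCurve",
    "InputFunction",
    "fit_sigmoid",
    "build_plasma_curve",
    "build_whole_blood_curve",
    "apply_parent_correction",
    "estimate_delay",
]

# Discrete-sample times (minutes) for the standard arterial protocol.  The
# first six define the plasma/blood ratio fit; all eight carry a measurable
# parent fraction (the 90-min sample, when drawn, supports plasma and whole
# blood only).
RATIO_FIT_TIMES_MIN = (3.0, 5.0, 10.0, 15.0, 20.0, 30.0)
DISCRETE_SAMPLE_TIMES_MIN = (3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0, 75.0)
LATE_MERGE_TIMES_MIN = (20.0, 30.0, 50.0, 60.0, 75.0)


@dataclass(frozen=True)
class BloodDataset:
    """Continuous and discrete arterial blood measurements.

    ``continuous_time`` is in seconds (the on-line detector grid, nominally
    0-900 s at 1 s); ``discrete_time`` is in minutes (syringe samples).
    """

    continuous_time: np.ndarray
    continuous_whole_blood: np.ndarray
    discrete_time: np.ndarray
    discrete_plasma: np.ndarray
    discrete_whole_blood: np.ndarray
    discrete_parent_fraction: np.ndarray

    def __post_init__(self):
        for name in ("continuous_time", "continuous_whole_blood", "discrete_time",
                     "discrete_plasma", "discrete_whole_blood",
                     "discrete_parent_fraction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.continuous_time) <= 0) or np.any(np.diff(self.discrete_time) <= 0):
            raise ValueError("time grids must be strictly increasing")
        for name in ("continuous_whole_blood", "discrete_plasma", "discrete_whole_blood"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        pf = self.discrete_parent_fraction
        if np.any(~np.isfinite(pf)) or np.any(pf < 0) or np.any(pf > 1):
            raise ValueError("parent fractions must lie in [0, 1]")

    @property
    def ratio_samples(self):
        """(times_min, plasma/whole-blood ratio) for the first six samples."""
        mask = np.isin(self.discrete_time, RATIO_FIT_TIMES_MIN)
        wb = self.discrete_whole_blood[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(wb > 0, self.discrete_plasma[mask] / wb, 1.0)
        return self.discrete_time[mask], ratio


def _logistic4(t, a, b, c, d):
    # value b at t=0, asymptote a as t -> inf (for d > 0)
    with np.errstate(divide="ignore"):
        return a + (b - a) / (1.0 + (np.asarray(t, dtype=float) / c) ** d)


@dataclass(frozen=True)
class SigmoidModel:
    """4-parameter logistic curve ``a + (b - a) / (1 + (t/c)^d)``.

    ``b`` is the value at t = 0 and ``a`` the late asymptote (for d > 0);
    ``c`` is the half-transition time and ``d`` the steepness.  ``rss`` is
    the residual sum of squares of the fit that produced the model.
    """

    a: float
    b: float
    c: float
    d: float
    rss: float = np.nan

    def __post_init__(self):
        if not (self.c > 0):
            raise ValueError("sigmoid half-transition time c must be positive")

    def __call__(self, t):
        return _logistic4(t, self.a, self.b, self.c, self.d)

    @classmethod
    def constant(cls, value: float) -> "SigmoidModel":
        return cls(a=value, b=value, c=1.0, d=1.0, rss=0.0)


def fit_sigmoid(times, values, init_strategy: str = "multistart",
                n_starts: int = 8, return_best_on_failure: bool = False,
                seed: int = 0) -> SigmoidModel:
    """Least-squares fit of the 4-parameter logistic to (times, values).

    Uses multiple bounded starts (varying the half-transition time and
    steepness sign) and keeps the solution with the smallest residual sum
    of squares; the fit is invariant to the ordering of the points.

    Parameters
    ----------
    times, values : array-like
        At least 5 finite points (4 free parameters + 1).
    init_strategy : {"multistart", "single"}
        "single" runs one start from data-driven initial values.
    return_best_on_failure : bool
        If no start converges, return the best candidate found instead of
        raising.

    Raises
    ------
    ValueError
        Fewer than 5 points or non-finite values.
    RuntimeError
        No start converged (unless ``return_best_on_failure``).
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError(f"sigmoid fit needs >= 5 points, got {t.size}")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
        raise ValueError("non-finite values in sigmoid fit input")
    order = np.argsort(t)
    t, v = t[order], v[order]

    if np.allclose(v, v[0]):
        return SigmoidModel.constant(float(v[0]))

    span = float(v.max() - v.min())
    t_mid = float(np.median(t))
    rng = np.random.default_rng(seed)
    starts = [(v[-1], v[0], t_mid, 3.0), (v[-1], v[0], t_mid, 1.0),
              (v[0], v[-1], t_mid, -3.0)]
    if init_strategy == "multistart":
        while len(starts) < n_starts:
            starts.append((
                v[-1] + span * rng.uniform(-0.5, 0.5),
                v[0] + span * rng.uniform(-0.5, 0.5),
                float(np.exp(rng.uniform(np.log(max(t[t > 0].min(), 1e-3)),
                                         np.log(t.max())))),
                rng.uniform(-8.0, 8.0),
            ))

    lo = [-np.inf, -np.inf, 1e-9, -50.0]
    hi = [np.inf, np.inf, 1e6, 50.0]
    best, best_rss = None, np.inf
    for p0 in starts:
        try:
            popt, _ = curve_fit(_logistic4, t, v, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((v - _logistic4(t, *popt)) ** 2))
        if rss < best_rss:
            best, best_rss = popt, rss
    if best is None:
        if return_best_on_failure:
            return SigmoidModel(v[-1], v[0], t_mid, 1.0, rss=np.inf)
        raise RuntimeError("sigmoid fit failed to converge from any start")
    a, b, c, d = best
    if d < 0:  # the parameterisation is symmetric under (a,b,d) -> (b,a,-d)
        a, b, d = b, a, -d
    return SigmoidModel(a, b, c, d, rss=best_rss)


@dataclass(frozen=True)
class TimeCurve:
    """A sampled time-activity curve with linear interpolation, time in s."""

    time: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        return np.interp(t, self.time, self.values, left=0.0)


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial plasma parent activity over the scan."""

    time: np.ndarray
    parent_plasma_activity: np.ndarray
    delay_applied: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.parent_plasma_activity, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(v < -1e-12) or np.any(~np.isfinite(v)):
            raise ValueError("parent plasma activity must be finite and non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "parent_plasma_activity", np.maximum(v, 0.0))

    def __call__(self, t):
        return np.interp(t, self.time, self.parent_plasma_activity, left=0.0)

    def shifted(self, delay_s: float) -> "InputFunction":
        """Input as seen at a site the bolus reaches ``delay_s`` later.

        Positive delay moves the curve to later times (zero-filled before
        arrival); the applied delay is accumulated in ``delay_applied``.
        """
        vals = np.interp(self.time - delay_s, self.time,
                         self.parent_plasma_activity, left=0.0)
        return InputFunction(self.time, vals,
                             delay_applied=self.delay_applied + delay_s,
                             meta=dict(self.meta))


def _merge_with_late_samples(cont_time_s, cont_values, blood: BloodDataset,
                             discrete_values) -> TimeCurve:
    late = [m for m in LATE_MERGE_TIMES_MIN if m in blood.discrete_time]
    missing = sorted(set(LATE_MERGE_TIMES_MIN) - set(late))
    if missing:
        warnings.warn(f"late discrete samples missing at {missing} min; "
                      "merging the available ones", stacklevel=3)
    keep = cont_time_s <= 15.0 * 60.0
    t = list(cont_time_s[keep])
    v = list(cont_values[keep])
    for m in late:
        ts = m * 60.0
        if ts <= t[-1]:
            continue
        idx = int(np.where(blood.discrete_time == m)[0][0])
        t.append(ts)
        v.append(float(discrete_values[idx]))
    return TimeCurve(np.asarray(t), np.asarray(v))


def build_plasma_curve(blood: BloodDataset, ratio_model: SigmoidModel) -> TimeCurve:
    """Total plasma activity over the whole scan.

    The continuous whole-blood curve is multiplied by the fitted
    plasma/whole-blood ratio sigmoid (evaluated in minutes) to give a
    continuous plasma curve over the first 15 minutes, which is then merged
    with the late discrete plasma samples (20, 30, 50, 60 and 75 min where
    present); interpolation between merged points is piecewise linear.
    """
    ratio = np.asarray(ratio_model(blood.continuous_time / 60.0), dtype=float)
    if np.any(ratio < 0):
        raise ValueError("ratio model produces negative plasma/blood ratios")
    cont_plasma = blood.continuous_whole_blood * ratio
    return _merge_with_late_samples(blood.continuous_time, cont_plasma,
                                    blood, blood.discrete_plasma)


def build_whole_blood_curve(blood: BloodDataset) -> TimeCurve:
    """Whole-blood activity over the whole scan (continuous + late samples).

    Used for the vascular (blood-volume) term of the tissue model.
    """
    return _merge_with_late_samples(blood.continuous_time,
                                    blood.continuous_whole_blood,
                                    blood, blood.discrete_whole_blood)


def apply_parent_correction(plasma_curve: TimeCurve,
                            parent_model: SigmoidModel) -> InputFunction:
    """Multiply total plasma activity by the fitted parent fraction.

    The parent-fraction sigmoid (fitted to the discrete parent-fraction
    measurements, evaluated in minutes) is clipped to [0, 1] before the
    pointwise product.
    """
    frac = np.clip(parent_model(plasma_curve.time / 60.0), 0.0, 1.0)
    return InputFunction(plasma_curve.time, plasma_curve.values * frac,
                         meta={"parent_model": parent_model})


def estimate_delay(input_function: InputFunction, whole_brain_tac,
                   frame_schedule, whole_blood=None,
                   search_grid=None, n_beta: int = 24) -> float:
    """Whole-brain bolus arrival delay via a spectral-fit grid search.

    For each candidate delay the input function (and blood curve, if given)
    is time-shifted and a coarse spectral fit of the whole-brain TAC is
    performed; the delay minimising the weighted residual sum of squares is
    returned.  An optimum on the grid boundary, or a flat objective, raises
    a warning.

    Parameters
    ----------
    search_grid : array-like of float, optional
        Candidate delays in seconds; default -30..30 s in 0.5 s steps.
    """
    from scipy.integrate import cumulative_trapezoid

    from .kinetics import (BETA_FAST_DEFAULT, BETA_SLOW_DEFAULT,
                           SpectralAnalysisModel, SpectralBasis, exp_conv)

    if search_grid is None:
        search_grid = np.arange(-30.0, 30.0 + 1e-9, 0.5)
    grid = np.asarray(search_grid, dtype=float)
    tac = np.asarray(whole_brain_tac, dtype=float)

    # Shifting the (zero-filled) input by d shifts its exponential
    # convolutions by d, so the dense convolution is computed once and each
    # candidate delay only re-windows its running integral over the frames.
    margin = float(np.max(np.abs(grid))) + 1.0
    step = 0.5
    betas = np.logspace(np.log10(BETA_SLOW_DEFAULT), np.log10(BETA_FAST_DEFAULT),
                        n_beta)
    dense_t = np.arange(0.0, frame_schedule.total_duration + margin, step)
    conv = exp_conv(dense_t, input_function(dense_t), betas)
    integral = np.vstack([np.zeros((1, n_beta)),
                          cumulative_trapezoid(conv, dense_t, axis=0)])
    curves = [integral]
    if whole_blood is not None:
        wb_dense = np.asarray(whole_blood(dense_t), dtype=float)
        curves.append(np.concatenate(
            [[0.0], cumulative_trapezoid(wb_dense, dense_t)])[:, None])

    rss = np.empty(grid.size)
    for i, d in enumerate(grid):
        cols = []
        for cur in curves:
            i_lo = np.array([np.interp(frame_schedule.frame_start - d, dense_t, cur[:, j], left=0.0)
                             for j in range(cur.shape[1])]).T
            i_hi = np.array([np.interp(frame_schedule.frame_end - d, dense_t, cur[:, j], left=0.0)
                             for j in range(cur.shape[1])]).T
            cols.append((i_hi - i_lo) / frame_schedule.frame_duration[:, None])
        basis = SpectralBasis(betas, cols[0],
                              cols[1][:, 0] if whole_blood is not None else None,
                              frame_schedule, meta={"delay": float(d)})
        rss[i] = SpectralAnalysisModel(tac, basis).fit().weighted_rss
    best = int(np.argmin(rss))
    spread = float(np.ptp(rss))
    if spread <= 1e-3 * float(np.mean(rss)):
        warnings.warn("delay objective is flat; estimate unreliable", stacklevel=2)
    elif best in (0, grid.size - 1):
        warnings.warn("delay optimum at search-grid boundary", stacklevel=2)
    return float(grid[best])
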