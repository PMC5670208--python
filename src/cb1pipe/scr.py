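"""Event-related skin-conductance response (SCR) scoring.

A fluctuation is scored for a stimulus when the conductance exhibits an
unambiguous rise of at least 0.01 microsiemens relative to the pre-stimulus
baseline, beginning (first rising data point) within 0.5-3 s after stimulus
onset.  The amplitude is the conductance difference from the rise onset to
the fluctuation peak; the latency is onset time minus stimulus time.  At
most one fluctuation (the first qualifying rise) is scored per stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SCRTrace", "SCRConfig", "detect_scr_events", "summarize_scr"]

AMPLITUDE_THRESHOLD_US = 0.01   # minimum unambiguous rise, microsiemens
RESPONSE_WINDOW_S = (0.5, 3.0)  # rise onset must fall in this post-stimulus window


@dataclass(frozen=True)
class SCRTrace:
    """Uniformly sampled skin-conductance trace in microsiemens."""

    sampling_rate: float  # Hz
    conductance: np.ndarray
    subject: str = ""
    condition: str = ""

    def __post_init__(self):
        if not (self.sampling_rate > 0):
            raise ValueError("sampling rate must be positive")
        c = np.asarray(self.conductance, dtype=float)
        if np.any(~np.isfinite(c)):
            raise ValueError("conductance must be finite")
        object.__setattr__(self, "conductance", c)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.conductance.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.conductance.size / self.sampling_rate


@dataclass(frozen=True)
class SCRConfig:
    """Scoring parameters.

    ``baseline_window_s`` is the width of the pre-stimulus mean used as
    baseline; ``smooth_window_s`` a moving-average width applied before
    differencing to suppress sensor noise (0 disables); ``window_anchor``
    selects whether the 0.5-3 s response window constrains the rise onset
    or the peak.
    """

    amplitude_threshold: float = AMPLITUDE_THRESHOLD_US
    window: tuple = RESPONSE_WINDOW_S
    baseline_window_s: float = 1.0
    smooth_window_s: float = 0.25
    window_anchor: str = "onset"
    max_rise_s: float = 5.0  # how far past the window a rise may peak

    def __post_init__(self):
        if self.window_anchor not in ("onset", "peak"):
            raise ValueError("window_anchor must be 'onset' or 'peak'")


def _smooth(x: np.ndarray, fs: float, width_s: float) -> np.ndarray:
    n = int(round(width_s * fs))
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    pad = np.pad(x, (n // 2, n - 1 - n // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_scr_events(trace: SCRTrace, stimuli: pd.DataFrame,
                      config: SCRConfig | None = None) -> pd.DataFrame:
    """Score stimulus-locked SCR fluctuations.

    Parameters
    ----------
    trace : SCRTrace
        Conductance trace; sampling rate must be at least 2 Hz.
    stimuli : DataFrame
        Columns ``onset_s`` and (optionally) ``valence``.
    config : SCRConfig, optional

    Returns
    -------
    DataFrame with one row per detected event: ``stimulus_index``,
    ``onset_latency``, ``amplitude``, ``peak_time``, ``rise_time`` and the
    stimulus ``valence``.  Stimuli whose scoring window extends past the
    end of the trace are skipped with a warning.
    """
    cfg = config or SCRConfig()
    if trace.sampling_rate < 2:
        raise ValueError("sampling rate must be at least 2 Hz for SCR scoring")
    fs = trace.sampling_rate
    sc = _smooth(trace.conductance, fs, cfg.smooth_window_s)
    t = trace.time
    diff = np.diff(sc)
    w_lo, w_hi = cfg.window

    rows = []
    for idx, stim in stimuli.reset_index(drop=True).iterrows():
        s = float(stim["onset_s"])
        if s + w_hi + (0.0 if cfg.window_anchor == "peak" else cfg.max_rise_s) \
                > trace.duration:
            warnings.warn(f"stimulus {idx} at {s:.1f}s too close to trace end; "
                          "skipped", stacklevel=2)
            continue
        b_lo = max(0.0, s - cfg.baseline_window_s)
        base_mask = (t >= b_lo) & (t < s)
        baseline = float(trace.conductance[base_mask].mean()) \
            if base_mask.any() else float(trace.conductance[0])

        # candidate rising runs are found on the smoothed trace over a
        # window widened by the smoothing half-width, then onset and peak
        # are refined on the raw trace and the 0.5-3 s rule applied to the
        # refined onset (or peak, per window_anchor)
        half = max(1, int(round(cfg.smooth_window_s * fs / 2))) \
            if cfg.smooth_window_s > 0 else 0
        lo = max(1, int(np.ceil((s + w_lo) * fs)) - half)
        hi = int(np.floor((s + w_hi) * fs)) + half
        raw = trace.conductance
        event = None
        for i in range(lo, min(hi + 1, diff.size)):
            if diff[i] <= 0 or diff[i - 1] > 0:
                continue  # not the start of a rising run
            j = i
            j_max = min(int((s + w_hi + cfg.max_rise_s) * fs), diff.size)
            while j + 1 < j_max and diff[j + 1] > 0:
                j += 1
            peak_sm = j + 1
            # refine on the raw trace: onset = last minimum just before the
            # rise; peak = maximum around the smoothed peak
            o_lo, o_hi = max(0, i - half), min(raw.size, i + half + 1)
            seg = raw[o_lo:o_hi]
            onset = o_lo + (seg.size - 1 - int(np.argmin(seg[::-1])))
            p_lo, p_hi = max(0, peak_sm - half), min(raw.size, peak_sm + half + 1)
            peak = p_lo + int(np.argmax(raw[p_lo:p_hi]))
            anchor = t[onset] if cfg.window_anchor == "onset" else t[peak]
            if not (s + w_lo <= anchor <= s + w_hi):
                continue
            amplitude = raw[peak] - raw[onset]
            if amplitude >= cfg.amplitude_threshold and \
                    raw[peak] - baseline >= cfg.amplitude_threshold:
                event = dict(stimulus_index=int(idx),
                             onset_latency=float(t[onset] - s),
                             amplitude=float(amplitude),
                             peak_time=float(t[peak]),
                             rise_time=float(t[peak] - t[onset]),
                             valence=stim.get("valence", ""))
                break
        if event is not None:
            rows.append(event)
    return pd.DataFrame(rows, columns=["stimulus_index", "onset_latency",
                                       "amplitude", "peak_time", "rise_time",
                                       "valence"])


def summarize_scr(events: pd.DataFrame, stimuli: pd.DataFrame,
                  grouping: str = "valence") -> pd.DataFrame:
    """Per-cell SCR counts, mean amplitudes and mean latencies.

    ``grouping`` is one of ``valence``, ``drug`` or ``valence x drug``; the
    grouping columns are taken from the stimulus table (``valence``) and,
    for drug, a ``condition`` column that must be present on ``stimuli``.
    Cells with no events report count 0 and missing (NaN) amplitude and
    latency rather than zeros.
    """
    keys = {"valence": ["valence"], "drug": ["condition"],
            "valence x drug": ["valence", "condition"]}
    if grouping not in keys:
        raise ValueError(f"unknown grouping {grouping!r}")
    cols = keys[grouping]
    for c in cols:
        if c not in stimuli.columns:
            raise ValueError(f"stimulus table lacks column {c!r}")
    stim = stimuli.reset_index(drop=True)
    merged = events.merge(stim[cols].reset_index(names="stimulus_index"),
                          on="stimulus_index", suffixes=("_ev", ""))
    out = []
    for cell, group in stim.groupby(cols, sort=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        sel = merged
        for c, v in zip(cols, cell):
            sel = sel[sel[c] == v]
        out.append({**dict(zip(cols, cell)),
                    "n_stimuli": len(group),
                    "count": len(sel),
                    "mean_amplitude": float(sel["amplitude"].mean()) if len(sel) else np.nan,
                    "mean_latency": float(sel["onset_latency"].mean()) if len(sel) else np.nan})
    return pd.DataFrame(out)
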