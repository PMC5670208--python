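"""PET frame schedules, statistical frame weights, and decay bookkeeping.

A dynamic PET acquisition is rebinned into contiguous time frames.  The
frame schedule carries, per frame, the start time, the duration ``L_i``
(seconds) and the scanner's rate of true coincidences ``T_i`` (counts/s),
from which the fitting weights ``w_i = L_i / T_i`` are formed: the variance
of a frame's reconstructed activity is approximately proportional to
``T_i / L_i``, so these weights are proportional to the reciprocal variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "decay_constant",
    "frame_weights",
    "meppep_frame_schedule",
]


def decay_constant(half_life_minutes: float) -> float:
    """Radioactive decay constant in s^-1 from a half-life in minutes.

    For carbon-11 (half-life 20.4 min) this evaluates to 5.663e-4 s^-1,
    the slowest physically meaningful tissue kinetic for an 11C tracer.

    Raises
    ------
    ValueError
        If the half-life is not strictly positive.
    """
    if not np.isfinite(half_life_minutes) or half_life_minutes <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_minutes}")
    return float(np.log(2.0) / (half_life_minutes * 60.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Timing and count-rate description of a dynamic PET acquisition.

    Parameters
    ----------
    frame_start : array of float
        Frame start times in seconds, strictly increasing.
    frame_duration : array of float
        Frame lengths ``L_i`` in seconds, all positive; frames must be
        contiguous and non-overlapping.
    trues_rate : array of float, optional
        True-coincidence rates ``T_i`` in counts/s, non-negative.  Defaults
        to 1 for every frame (uniform weights equal to frame durations).
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray
    trues_rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("frame_start and frame_duration must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-6):
            raise ValueError("frames must be contiguous and non-overlapping")
        trues = self.trues_rate
        if trues is None:
            trues = np.ones_like(dur)
        else:
            trues = np.asarray(trues, dtype=float)
            if trues.shape != dur.shape:
                raise ValueError("trues_rate must match the number of frames")
            if np.any(trues < 0):
                raise ValueError("trues rates must be non-negative")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        object.__setattr__(self, "trues_rate", trues)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration(self) -> float:
        """Scan length in seconds (end of last frame)."""
        return float(self.frame_end[-1])

    def with_trues(self, trues_rate) -> "FrameSchedule":
        return FrameSchedule(self.frame_start, self.frame_duration, trues_rate)


def frame_weights(schedule: FrameSchedule) -> np.ndarray:
    """Reciprocal-variance frame weights ``w_i = L_i / T_i``.

    Frames with a zero trues rate would have infinite nominal variance; they
    receive weight 0 (excluded from the fit) with a warning.
    """
    trues = schedule.trues_rate
    weights = np.zeros(schedule.n_frames)
    zero = trues == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} frame(s) with zero trues rate given weight 0",
            stacklevel=2,
        )
    weights[~zero] = schedule.frame_duration[~zero] / trues[~zero]
    return weights


# Rebinning used for the 95-min [11C]MePPEP acquisitions: one 30-s background
# frame, then 6x10 s, 3x20 s, 3x30 s, 4x60 s, 6x120 s, 9x300 s, 3x600 s.
_MEPPEP_REBINNING = ((30.0, 1), (10.0, 6), (20.0, 3), (30.0, 3),
                     (60.0, 4), (120.0, 6), (300.0, 9), (600.0, 3))


def meppep_frame_schedule(trues_rate=None) -> FrameSchedule:
    """The 35-frame, 95-minute [11C]MePPEP rebinning schedule."""
    durations = np.concatenate([np.full(n, d) for d, n in _MEPPEP_REBINNING])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations, trues_rate)
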