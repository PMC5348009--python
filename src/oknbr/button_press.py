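"""Button-press preprocessing: smoothing, consistency, labels and latencies.

The raw key record ``RawBP(t)`` takes values -1 (left key), +1 (right key)
and 0 (no key, or both keys at once).  It is smoothed with a 100-ms boxcar
kernel into the continuous ``BP(t)``; the dominant-percept label of a trial
is the sign of the mean ``BP`` over the first 1.5 s; consistency ``C(t)`` is
the indicator of ``BP(t) * dir >= 0.5`` where ``dir`` is the stimulus
direction (non-rivalrous) or the trial's dominant label (rivalrous).

With the 100-ms kernel at 60 Hz, ``BP`` crosses 0.5 roughly two samples
(~33 ms) after a clean press onset, so the first *consistent* press time
carries a small systematic offset relative to the raw first press.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_io import ButtonTrace

__all__ = [
    "BP_KERNEL_S",
    "LABEL_WINDOW_S",
    "CONSISTENCY_THRESHOLD",
    "BPTrace",
    "TrialLabel",
    "ConsistencyTrace",
    "boxcar_smooth",
    "compute_bp",
    "dominant_label",
    "consistency",
    "first_press_time",
    "first_consistent_press_time",
    "response_accuracy",
]

#: boxcar kernel width applied to RawBP (and, in okn.py, to gaze position)
BP_KERNEL_S = 0.1
#: window over which BP is averaged to label a trial's dominant direction
LABEL_WINDOW_S = 1.5
#: inclusive threshold on BP * dir defining a consistent press
CONSISTENCY_THRESHOLD = 0.5


@dataclass
class BPTrace:
    """Smoothed button state; ``bp`` is real in [-1, 1]."""

    time_s: np.ndarray
    bp: np.ndarray


@dataclass(frozen=True)
class TrialLabel:
    """Dominant-direction label of one trial.

    ``label_dir`` is ``sign(p_bp)``; ``None`` when ``p_bp`` is exactly zero
    (the trial is left unlabelled and excluded from rivalrous analyses).
    """

    p_bp: float

    @property
    def label_dir(self) -> int | None:
        if self.p_bp > 0:
            return +1
        if self.p_bp < 0:
            return -1
        return None


@dataclass
class ConsistencyTrace:
    """Binary consistency ``c(t) = 1{bp(t) * dir >= 0.5}``."""

    time_s: np.ndarray
    c: np.ndarray


def boxcar_smooth(values: np.ndarray, width_s: float, rate_hz: float) -> np.ndarray:
    """Centred moving average over ``round(width_s * rate_hz)`` samples.

    The window is truncated and renormalised at the edges, so constant
    signals are preserved exactly everywhere, including the boundaries.
    For an even window length the extra sample sits on the earlier-time side
    (window ``i - n//2 .. i + n//2 - 1`` around sample ``i``).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot smooth an empty series")
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    n = max(1, round(width_s * rate_hz))
    if n == 1:
        return values.copy()
    kernel = np.ones(n)
    # full convolution sliced so out[i] averages values[i - n//2 : i + n - n//2]
    sel = slice(n - n // 2 - 1, n - n // 2 - 1 + values.size)
    num = np.convolve(values, kernel)[sel]
    den = np.convolve(np.ones_like(values), kernel)[sel]
    return num / den


def compute_bp(raw: ButtonTrace) -> BPTrace:
    """Smooth a raw button segment into ``BP(t)`` (100-ms boxcar)."""
    bp = boxcar_smooth(raw.raw_bp.astype(float), BP_KERNEL_S, raw.rate_hz)
    return BPTrace(time_s=raw.time_s.copy(), bp=bp)


def dominant_label(bp: BPTrace) -> TrialLabel:
    """Label a trial by the mean of ``BP`` over [0, 1.5] s from onset."""
    mask = (bp.time_s >= 0.0) & (bp.time_s <= LABEL_WINDOW_S)
    if not mask.any():
        raise ValueError("BP trace does not cover [0, 1.5] s")
    return TrialLabel(p_bp=float(np.mean(bp.bp[mask])))


def consistency(bp: BPTrace, direction: int) -> ConsistencyTrace:
    """``c(t) = 1`` iff ``bp(t) * direction >= 0.5`` (inclusive threshold)."""
    if direction not in (-1, 1):
        raise ValueError(f"direction must be -1 or +1, got {direction!r}")
    c = (bp.bp * direction >= CONSISTENCY_THRESHOLD).astype(float)
    return ConsistencyTrace(time_s=bp.time_s.copy(), c=c)


def first_press_time(raw: ButtonTrace) -> float | None:
    """Timestamp of the first raw sample with any key down at t >= 0.

    The absolute first press, disregarding any later switches (including
    corrective ones).  No sub-sample interpolation: 60-Hz resolution matches
    the reporting precision of the latencies.
    """
    mask = (raw.time_s >= 0.0) & (raw.raw_bp != 0)
    idx = np.flatnonzero(mask)
    return float(raw.time_s[idx[0]]) if idx.size else None


def first_consistent_press_time(bp: BPTrace, label_dir: int | None) -> float | None:
    """Earliest t >= 0 with ``bp(t) * label_dir >= 0.5``; None if never."""
    if label_dir not in (-1, 1):
        raise ValueError("label_dir undefined; trial cannot be scored")
    mask = (bp.time_s >= 0.0) & (bp.bp * label_dir >= CONSISTENCY_THRESHOLD)
    idx = np.flatnonzero(mask)
    return float(bp.time_s[idx[0]]) if idx.size else None


def response_accuracy(c: ConsistencyTrace, t_first: float | None) -> float | None:
    """Mean consistency from the first press to 1.5 s after onset.

    Undefined (None) when there was no press or the first press came at or
    after 1.5 s.
    """
    if t_first is None or t_first >= LABEL_WINDOW_S:
        return None
    mask = (c.time_s >= t_first) & (c.time_s <= LABEL_WINDOW_S)
    if not mask.any():
        return None
    return float(np.mean(c.c[mask]))
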