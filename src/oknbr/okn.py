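"""Slow-phase optokinetic-nystagmus (OKN) velocity extraction.

OKN alternates slow phases, whose velocity tracks the perceived motion, with
quick resetting phases.  The analysis signal is the slow-phase velocity:

1. blinks (invalid/missing samples) and saccade-like quick phases are
   detected — quick phases by velocity/acceleration thresholds on a lightly
   median-filtered position trace;
2. each removed period, padded by 10 ms on both sides, is bridged: the padded
   span is held at the position just before it, and everything after is
   shifted so the trace is continuous ("integrated OKN") — its derivative is
   then pure slow-phase velocity;
3. the integrated trace is boxcar-smoothed (100 ms), differentiated
   sample-to-sample, and the instantaneous velocity smoothed again with the
   same kernel.

The printed detection thresholds (6 deg/s, 1 deg/s^2) are the defaults.  The
acceleration figure taken literally is far below real saccadic accelerations
(thousands of deg/s^2) and, on noisy data, flags everything; both thresholds
are therefore plain parameters, and the synthetic-cohort presets use a
velocity threshold above the slow-phase speed ceiling (slow phases at a gain
of 1 move at 22.3 deg/s, above the printed 6 deg/s) with the acceleration
criterion effectively disabled.  Quick phases are orders of magnitude faster
than any slow phase, so any threshold between the two separates them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .button_press import BP_KERNEL_S, boxcar_smooth
from .session_io import (
    Block,
    CoverageError,
    GazeTrace,
    POST_ONSET_S,
    PRE_ONSET_S,
    Trial,
)

__all__ = [
    "SACCADE_V_THRESH_DEG_S",
    "SACCADE_A_THRESH_DEG_S2",
    "BRIDGE_PAD_S",
    "ArtifactKind",
    "ArtifactInterval",
    "IntegratedOKN",
    "VelocityTrace",
    "FirstTrialOfBlock",
    "detect_artifacts",
    "integrate_okn",
    "slow_phase_velocity",
    "trial_velocity",
    "artifact_time_in_window",
]

#: printed defaults for quick-phase/saccade detection
SACCADE_V_THRESH_DEG_S = 6.0
SACCADE_A_THRESH_DEG_S2 = 1.0
#: padding around each removed period before bridging
BRIDGE_PAD_S = 0.010


class ArtifactKind(enum.Enum):
    BLINK_OR_MISSING = "BLINK_OR_MISSING"
    SACCADE = "SACCADE"


@dataclass(frozen=True)
class ArtifactInterval:
    start_s: float
    end_s: float
    kind: ArtifactKind

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError("interval must have start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class IntegratedOKN:
    """Bridged ('integrated') horizontal position whose derivative is
    slow-phase velocity."""

    time_s: np.ndarray
    f_deg: np.ndarray
    removed: list[ArtifactInterval] = field(default_factory=list)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))


@dataclass
class VelocityTrace:
    """Signed slow-phase velocity (deg/s, rightward positive)."""

    time_s: np.ndarray
    v_deg_s: np.ndarray


class FirstTrialOfBlock(ValueError):
    """Raised when a velocity trace is requested for the first trial of a
    block: no pre-onset fixation exists for it and it is excluded."""


def detect_artifacts(
    g: GazeTrace,
    v_thresh: float = SACCADE_V_THRESH_DEG_S,
    a_thresh: float = SACCADE_A_THRESH_DEG_S2,
) -> list[ArtifactInterval]:
    """Find blink/missing and saccade-like periods in a gaze trace.

    Invalid or non-finite samples form BLINK_OR_MISSING intervals.  Runs
    where the central-difference |velocity| exceeds ``v_thresh`` or
    |acceleration| exceeds ``a_thresh`` (OR of the two criteria — the
    conservative reading for artifact removal) form SACCADE intervals;
    derivatives are taken on a 3-sample median-filtered position with missing
    samples linearly bridged, so single-sample tracker noise does not trip
    the thresholds and blink edges do not masquerade as saccades.  Intervals
    of either kind that overlap or touch are merged; a merged interval
    containing any missing sample is labelled BLINK_OR_MISSING.
    """
    n = len(g)
    if n < 3:
        raise ValueError("need at least 3 samples to estimate acceleration")
    t = g.time_s
    dt = float(np.median(np.diff(t)))

    missing = ~g.valid | ~np.isfinite(g.x_deg)
    x = g.x_deg.copy()
    if missing.any():
        if missing.all():
            return [_interval_from_run(t, 0, n - 1, dt, ArtifactKind.BLINK_OR_MISSING)]
        x[missing] = np.interp(t[missing], t[~missing], x[~missing])
    x = _median3(x)

    v = np.gradient(x, t)
    a = np.gradient(v, t)
    saccade = (np.abs(v) > v_thresh) | (np.abs(a) > a_thresh)

    intervals: list[ArtifactInterval] = []
    for flags, kind in ((missing, ArtifactKind.BLINK_OR_MISSING),
                        (saccade, ArtifactKind.SACCADE)):
        for i0, i1 in _runs(flags):
            intervals.append(_interval_from_run(t, i0, i1, dt, kind))
    return merge_intervals(intervals)


def _median3(x: np.ndarray) -> np.ndarray:
    """3-sample running median with edge replication (scipy's medfilt
    zero-pads, which fabricates steps at the trace ends)."""
    padded = np.concatenate(([x[0]], x, [x[-1]]))
    stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    return np.median(stacked, axis=0)


def _interval_from_run(t, i0, i1, dt, kind) -> ArtifactInterval:
    # half-sample margins so a k-sample run spans k*dt and adjacent runs touch
    return ArtifactInterval(t[i0] - dt / 2, t[i1] + dt / 2, kind)


def _runs(flags: np.ndarray):
    """Yield (first, last) index pairs of maximal True runs."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [idx.size - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def merge_intervals(intervals: list[ArtifactInterval]) -> list[ArtifactInterval]:
    """Merge overlapping or touching intervals; blink absorbs saccade."""
    if not intervals:
        return []
    out: list[ArtifactInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.start_s, i.end_s)):
        if out and iv.start_s <= out[-1].end_s:
            prev = out.pop()
            kind = (
                ArtifactKind.BLINK_OR_MISSING
                if ArtifactKind.BLINK_OR_MISSING in (prev.kind, iv.kind)
                else ArtifactKind.SACCADE
            )
            out.append(ArtifactInterval(prev.start_s, max(prev.end_s, iv.end_s), kind))
        else:
            out.append(iv)
    return out


def integrate_okn(g: GazeTrace, intervals: list[ArtifactInterval]) -> IntegratedOKN:
    """Bridge removed periods into a continuous 'integrated OKN' trace.

    For the i-th removed period [Rs, Re] (processed in time order), positions
    over [Rs - 10 ms, Re + 10 ms] are replaced by the constant F(Rs - 10 ms)
    and all later samples are shifted by F(Rs - 10 ms) - F(Re + 10 ms), so
    the trace is continuous at every junction.  Padded spans that overlap are
    merged first so the shift accumulation is well defined; padding that
    would extend before the first sample is clamped to it.
    """
    t = g.time_s
    f = g.x_deg.astype(float).copy()
    merged = merge_intervals(
        [
            ArtifactInterval(iv.start_s - BRIDGE_PAD_S, iv.end_s + BRIDGE_PAD_S, iv.kind)
            for iv in intervals
        ]
    )
    for iv in merged:
        a = int(np.searchsorted(t, iv.start_s, "right") - 1)  # last sample <= Rs-10ms
        a = max(a, 0)
        b = int(np.searchsorted(t, iv.end_s, "left"))  # first sample >= Re+10ms
        if b >= len(t):
            f[a:] = f[a]
            continue
        shift = f[a] - f[b]
        f[a:b] = f[a]
        f[b:] += shift
    return IntegratedOKN(time_s=t.copy(), f_deg=f, removed=list(intervals))


def slow_phase_velocity(i: IntegratedOKN) -> VelocityTrace:
    """Doubly smoothed derivative of the integrated OKN.

    boxcar(100 ms) -> neighbouring-sample difference x rate -> boxcar
    (100 ms).  The one-sample-short difference is re-aligned and padded by
    edge replication so the velocity trace keeps the position timestamps.
    """
    rate = i.rate_hz
    f_s = boxcar_smooth(i.f_deg, BP_KERNEL_S, rate)
    dv = np.diff(f_s) * rate
    # midpoint-aligned diff, padded back to full length by edge replication
    v_inst = np.empty_like(f_s)
    v_inst[0] = dv[0]
    v_inst[-1] = dv[-1]
    v_inst[1:-1] = 0.5 * (dv[:-1] + dv[1:])
    v = boxcar_smooth(v_inst, BP_KERNEL_S, rate)
    return VelocityTrace(time_s=i.time_s.copy(), v_deg_s=v)


def trial_velocity(
    block: Block,
    trial: Trial,
    v_thresh: float = SACCADE_V_THRESH_DEG_S,
    a_thresh: float = SACCADE_A_THRESH_DEG_S2,
    *,
    velocity: VelocityTrace | None = None,
) -> VelocityTrace:
    """Slow-phase velocity of one trial on [-1, 2] s around onset.

    The full block trace is processed (detection, bridging, smoothing) and
    then windowed, so the smoothing kernels never see window edges.  Pass a
    precomputed block-level ``velocity`` to avoid recomputing it per trial.
    Raises :class:`FirstTrialOfBlock` for the first trial of a block.
    """
    if trial.first_of_block:
        raise FirstTrialOfBlock(
            f"block {trial.block_index}: first trial has no pre-onset fixation"
        )
    if velocity is None:
        intervals = detect_artifacts(block.gaze, v_thresh, a_thresh)
        velocity = slow_phase_velocity(integrate_okn(block.gaze, intervals))
    t = velocity.time_s
    lo, hi = trial.onset_s + PRE_ONSET_S, trial.onset_s + POST_ONSET_S
    dt = float(np.median(np.diff(t)))
    if lo < t[0] - dt / 2 or hi > t[-1] + dt / 2:
        raise CoverageError(f"velocity trace does not cover [{lo:.3f}, {hi:.3f}] s")
    rel = t - trial.onset_s
    i0 = np.searchsorted(rel, PRE_ONSET_S - dt / 2, "left")
    i1 = np.searchsorted(rel, POST_ONSET_S - dt / 2, "left")
    return VelocityTrace(time_s=rel[i0:i1], v_deg_s=velocity.v_deg_s[i0:i1])


def artifact_time_in_window(
    intervals: list[ArtifactInterval], start_s: float, end_s: float
) -> float:
    """Total (unpadded) artifact time intersected with [start_s, end_s]."""
    tot = 0.0
    for iv in intervals:
        tot += max(0.0, min(iv.end_s, end_s) - max(iv.start_s, start_s))
    return tot
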