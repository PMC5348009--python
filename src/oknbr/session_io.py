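"""Reading, writing and windowing of gaze, button and trial-event streams.

The on-disk formats are three tab-separated tables per session:

* gaze TSV: ``time_s``, ``x_deg``, ``y_deg``, ``valid`` (0/1), nominal 300 Hz;
* buttons TSV: ``time_s``, ``raw_bp`` (-1 left, +1 right, 0 none-or-double),
  nominal 60 Hz;
* events TSV: ``block``, ``trial``, ``onset_s``, ``condition`` (``L``/``R``/
  ``RIV``).

Positions are degrees of visual angle with 0 at the stimulus centre and
rightward positive; the same left = -1 / right = +1 sign convention is used
for stimulus direction, button state and every derived signal.  Lines
starting with ``#`` are ignored in all three files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Group",
    "SessionState",
    "GazeTrace",
    "ButtonTrace",
    "Trial",
    "Block",
    "Session",
    "SchemaError",
    "DataError",
    "CoverageError",
    "TRIAL_S",
    "ITI_S",
    "PRE_ONSET_S",
    "POST_ONSET_S",
    "load_gaze",
    "load_buttons",
    "load_events",
    "load_session",
    "write_gaze",
    "write_buttons",
    "write_events",
    "segment",
    "pixels_to_degrees",
]

#: protocol constants: 2-s stimulus, 1-s blank, analysis window [-1, 2] s
TRIAL_S = 2.0
ITI_S = 1.0
PRE_ONSET_S = -1.0
POST_ONSET_S = 2.0

#: at most this many blocks of a session enter the analysis
MAX_ANALYSIS_BLOCKS = 7


class SchemaError(ValueError):
    """A required column is missing or a field has the wrong type."""


class DataError(ValueError):
    """File parsed but violates a data invariant (e.g. non-monotone time)."""


class CoverageError(ValueError):
    """A trial's analysis window is not covered by the recorded traces."""


class Condition(enum.Enum):
    NONRIV_LEFT = "L"
    NONRIV_RIGHT = "R"
    RIVALROUS = "RIV"

    @property
    def stim_dir(self) -> int | None:
        if self is Condition.NONRIV_LEFT:
            return -1
        if self is Condition.NONRIV_RIGHT:
            return +1
        return None

    @property
    def rivalrous(self) -> bool:
        return self is Condition.RIVALROUS


class Group(enum.Enum):
    CONTROL = "CONTROL"
    PD = "PD"


class SessionState(enum.Enum):
    NA = "NA"
    ON_MED = "ON_MED"
    OFF_MED = "OFF_MED"
    ON_DBS = "ON_DBS"
    OFF_DBS = "OFF_DBS"


@dataclass
class GazeTrace:
    """Uniformly sampled horizontal/vertical gaze position in degrees."""

    time_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        _check_monotone(self.time_s)

    @property
    def rate_hz(self) -> float:
        return _uniform_rate(self.time_s)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class ButtonTrace:
    """Tri-state key record: -1 left, +1 right, 0 none-or-double."""

    time_s: np.ndarray
    raw_bp: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.raw_bp = np.asarray(self.raw_bp, dtype=int)
        _check_monotone(self.time_s)
        bad = ~np.isin(self.raw_bp, (-1, 0, 1))
        if bad.any():
            raise DataError(
                f"raw_bp outside {{-1, 0, 1}} at row {int(np.flatnonzero(bad)[0])}"
            )

    @property
    def rate_hz(self) -> float:
        return _uniform_rate(self.time_s)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class Trial:
    block_index: int
    trial_index_in_block: int  # 0-based
    onset_s: float
    condition: Condition

    @property
    def stim_dir(self) -> int | None:
        """-1 / +1 for non-rivalrous trials, None for rivalrous ones."""
        return self.condition.stim_dir

    @property
    def first_of_block(self) -> bool:
        """First trial of a block; excluded from eye-movement analyses."""
        return self.trial_index_in_block == 0


@dataclass
class Block:
    index: int
    gaze: GazeTrace
    buttons: ButtonTrace
    trials: list[Trial]


@dataclass
class Session:
    subject_id: str
    group: Group
    state: SessionState
    blocks: list[Block] = field(default_factory=list)

    def iter_trials(self):
        for block in self.blocks:
            yield from block.trials


def _check_monotone(t: np.ndarray) -> None:
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise DataError(f"time not strictly increasing at row {int(bad[0]) + 1}")


def _uniform_rate(t: np.ndarray) -> float:
    """Sampling rate of a nominally uniform time base (interval uniform to 1%)."""
    dt = np.diff(t)
    if dt.size == 0:
        raise DataError("trace has fewer than 2 samples")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise DataError("sampling interval varies by more than 1%")
    return 1.0 / med


def _read_tsv(
    path, columns: dict[str, type], nan_ok: frozenset[str] = frozenset()
) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", encoding="utf-8", float_precision="round_trip"
    )
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    # coerce numerics; malformed rows are reported and dropped.  Missing
    # values are legitimate only in nan_ok columns (e.g. position during a
    # blink); unparseable text is malformed anywhere.
    numeric = [c for c, typ in columns.items() if typ in (float, int)]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = (coerced.isna() & df[numeric].notna()).any(axis=1)
    for c in numeric:
        if c not in nan_ok:
            bad |= coerced[c].isna()
    n_bad = int(bad.sum())
    if n_bad:
        import warnings

        warnings.warn(f"{path}: dropped {n_bad} malformed row(s)", stacklevel=3)
    df = df.loc[~bad].reset_index(drop=True)
    df[numeric] = coerced.loc[~bad].reset_index(drop=True)
    return df


def load_gaze(path) -> GazeTrace:
    df = _read_tsv(
        path,
        {"time_s": float, "x_deg": float, "y_deg": float, "valid": int},
        nan_ok=frozenset({"x_deg", "y_deg"}),
    )
    return GazeTrace(
        time_s=df["time_s"].to_numpy(),
        x_deg=df["x_deg"].to_numpy(),
        y_deg=df["y_deg"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
    )


def load_buttons(path) -> ButtonTrace:
    df = _read_tsv(path, {"time_s": float, "raw_bp": int})
    return ButtonTrace(time_s=df["time_s"].to_numpy(), raw_bp=df["raw_bp"].to_numpy())


def load_events(path) -> list[Trial]:
    df = _read_tsv(path, {"block": int, "trial": int, "onset_s": float, "condition": str})
    trials = []
    for row in df.itertuples(index=False):
        try:
            cond = Condition(str(row.condition))
        except ValueError:
            raise SchemaError(
                f"{path}: unknown condition {row.condition!r} "
                f"(expected one of L, R, RIV)"
            ) from None
        trials.append(
            Trial(
                block_index=int(row.block),
                trial_index_in_block=int(row.trial),
                onset_s=float(row.onset_s),
                condition=cond,
            )
        )
    return trials


def write_gaze(path, trace: GazeTrace) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "x_deg": trace.x_deg,
            "y_deg": trace.y_deg,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_buttons(path, trace: ButtonTrace) -> None:
    df = pd.DataFrame({"time_s": trace.time_s, "raw_bp": trace.raw_bp})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_events(path, trials: Sequence[Trial]) -> None:
    df = pd.DataFrame(
        {
            "block": [t.block_index for t in trials],
            "trial": [t.trial_index_in_block for t in trials],
            "onset_s": [t.onset_s for t in trials],
            "condition": [t.condition.value for t in trials],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_session(
    gaze_path,
    button_path,
    events_path,
    meta: dict | None = None,
) -> Session:
    """Load one session from its three TSV files and segment it into blocks.

    ``meta`` may carry ``subject_id``, ``group`` and ``state``.  Every trial
    window ``[onset - 1 s, onset + 2 s]`` must be covered by both traces
    (raises :class:`CoverageError` naming the first offending trial), and the
    button trace must further cover the following inter-trial interval, which
    the trial-rejection rules inspect.
    """
    meta = meta or {}
    gaze = load_gaze(gaze_path)
    buttons = load_buttons(button_path)
    trials = load_events(events_path)
    if not trials:
        raise DataError(f"{events_path}: no trials")

    for tr in trials:
        lo, hi = tr.onset_s + PRE_ONSET_S, tr.onset_s + POST_ONSET_S
        if lo < gaze.time_s[0] or hi > gaze.time_s[-1]:
            raise CoverageError(
                f"gaze trace does not cover window [{lo:.3f}, {hi:.3f}] s of "
                f"block {tr.block_index} trial {tr.trial_index_in_block}"
            )
        if lo < buttons.time_s[0] or tr.onset_s + TRIAL_S + ITI_S > buttons.time_s[-1]:
            raise CoverageError(
                f"button trace does not cover window of "
                f"block {tr.block_index} trial {tr.trial_index_in_block}"
            )

    session = Session(
        subject_id=str(meta.get("subject_id", "unknown")),
        group=Group(meta.get("group", "CONTROL")),
        state=SessionState(meta.get("state", "NA")),
    )
    block_ids = sorted({t.block_index for t in trials})[:MAX_ANALYSIS_BLOCKS]
    for b in block_ids:
        btrials = sorted(
            (t for t in trials if t.block_index == b),
            key=lambda t: t.trial_index_in_block,
        )
        lo = btrials[0].onset_s + PRE_ONSET_S
        hi = btrials[-1].onset_s + TRIAL_S + ITI_S
        session.blocks.append(
            Block(
                index=b,
                gaze=_slice_trace(gaze, lo, hi),
                buttons=_slice_trace(buttons, lo, hi),
                trials=btrials,
            )
        )
    return session


def _slice_trace(trace, lo: float, hi: float):
    t = trace.time_s
    i0, i1 = np.searchsorted(t, lo, "left"), np.searchsorted(t, hi, "right")
    if isinstance(trace, GazeTrace):
        return GazeTrace(t[i0:i1], trace.x_deg[i0:i1], trace.y_deg[i0:i1], trace.valid[i0:i1])
    return ButtonTrace(t[i0:i1], trace.raw_bp[i0:i1])


def segment(trace, onset_s: float, t_min: float, t_max: float):
    """Window a trace around a trial onset, re-expressing time relative to it.

    Returns a trace of the same kind whose samples satisfy
    ``t_min <= t_rel < t_max``.  Raises :class:`CoverageError` if the window
    extends beyond the trace.
    """
    t = trace.time_s
    lo, hi = onset_s + t_min, onset_s + t_max
    # half-sample tolerance so float jitter on uniform grids does not matter
    eps = 0.5 / _uniform_rate(t)
    if lo < t[0] - eps or hi > t[-1] + eps:
        raise CoverageError(
            f"window [{lo:.4f}, {hi:.4f}] s outside trace span "
            f"[{t[0]:.4f}, {t[-1]:.4f}] s"
        )
    rel = t - onset_s
    i0 = np.searchsorted(rel, t_min - eps, "left")
    i1 = np.searchsorted(rel, t_max - eps, "left")
    if isinstance(trace, GazeTrace):
        return GazeTrace(rel[i0:i1], trace.x_deg[i0:i1], trace.y_deg[i0:i1], trace.valid[i0:i1])
    return ButtonTrace(rel[i0:i1], trace.raw_bp[i0:i1])


def pixels_to_degrees(
    x_px: np.ndarray,
    *,
    screen_width_px: float,
    screen_width_cm: float,
    viewing_distance_cm: float,
    center_px: float | None = None,
) -> np.ndarray:
    """Convert horizontal screen pixels to degrees of visual angle.

    Uses the exact arctangent mapping around the screen centre (or
    ``center_px``); rightward positive.  The analysis core is device-free and
    works in degrees throughout, so this helper is only needed when importing
    recordings stored in screen coordinates.
    """
    x_px = np.asarray(x_px, dtype=float)
    if center_px is None:
        center_px = screen_width_px / 2.0
    cm_per_px = screen_width_cm / screen_width_px
    offset_cm = (x_px - center_px) * cm_per_px
    return np.degrees(np.arctan2(offset_cm, viewing_distance_cm))
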