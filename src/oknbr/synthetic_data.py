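"""Synthetic sessions with known ground truth for every pipeline stage.

Each simulated session follows the study protocol: blocks of 20 trials
(2-s moving-grating stimulus + 1-s blank), 25% non-rivalrous-left, 25%
non-rivalrous-right and 50% rivalrous per block in random order, gratings at
22.3 deg/s, gaze sampled at 300 Hz and buttons at 60 Hz, with 7 blocks per
session entering the analysis.

The generative model per trial:

* a latent percept path — the stimulus direction for non-rivalrous trials;
  for rivalrous trials an initial dominant direction (fair coin by default)
  that flips at Poisson-hazard switch times;
* gaze: slow-phase velocity ``okn_gain x 22.3 deg/s`` in the percept
  direction, delayed by the oculomotor latency at stimulus onset *and*
  offset (OKN persists briefly after the grating disappears), integrated to
  position, with single-sample quick-phase resets whenever eccentricity
  passes a trigger, plus blinks (invalid samples) and Gaussian position
  noise;
* buttons: a press in the percept direction at onset + a Gaussian reaction
  time, following percept switches with fresh reaction times, with
  configurable rates of initial wrong-key presses, lapses (no press at all)
  and failures to release during the inter-trial interval.

Quick phases are near-instant (one sample, ~1200 deg/s at the default
amplitude), far above any slow-phase speed, so a velocity threshold between
the slow-phase ceiling and the quick-phase speed separates the two cleanly;
``recommended_v_thresh`` returns such a threshold for a config.

All randomness flows from ``rng_seed`` through one
:class:`numpy.random.SeedSequence` that spawns one child stream per block
(consumed in a fixed order within the block), so runs are byte-identical
for a given seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .session_io import (
    Block,
    ButtonTrace,
    Condition,
    GazeTrace,
    Group,
    ITI_S,
    Session,
    SessionState,
    TRIAL_S,
    Trial,
    write_buttons,
    write_events,
    write_gaze,
)

__all__ = [
    "SimConfig",
    "TrialTruth",
    "GroundTruth",
    "SimulatedSession",
    "simulate_session",
    "preset",
    "recommended_v_thresh",
]

STIM_SPEED_DEG_S = 22.3


@dataclass
class SimConfig:
    """Parameters of the generative model (all rates per second).

    Defaults describe a healthy control: OKN gain 0.4 (slow phases near
    9 deg/s — OKN without a fixation point runs well below stimulus speed),
    ~0.48-s mean first-press reaction time, modest error/lapse/hold rates.
    """

    rng_seed: int = 0
    n_blocks: int = 7
    trials_per_block: int = 20
    trial_s: float = TRIAL_S
    iti_s: float = ITI_S
    mix: tuple[float, float, float] = (0.25, 0.25, 0.50)  # L, R, RIV
    stim_speed_deg_s: float = STIM_SPEED_DEG_S
    gaze_rate_hz: float = 300.0
    button_rate_hz: float = 60.0
    okn_gain: float = 0.40
    okn_latency_s: float = 0.12
    quickphase_amplitude_deg: float = 6.0
    quickphase_trigger_deg: float = 3.0
    blink_rate_hz: float = 0.10
    blink_dur_mean_s: float = 0.18
    blink_dur_sd_s: float = 0.04
    gaze_noise_sd_deg: float = 0.05
    press_latency_mean_s: float = 0.482
    press_latency_sd_s: float = 0.08
    press_error_rate: float = 0.05
    press_error_dur_s: float = 0.067
    switch_hazard_per_s: float = 0.25
    lapse_rate: float = 0.02
    hold_through_iti_rate: float = 0.02
    rivalry_right_bias: float = 0.5
    pre_roll_s: float = 1.0  # recording starts this long before each block's first onset

    def validate(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix must sum to 1")
        if not 0 < self.okn_gain <= 1.5:
            raise ValueError("okn_gain must be in (0, 1.5]")
        if self.okn_latency_s >= self.trial_s:
            raise ValueError("okn_latency_s must be shorter than the trial")
        for name in (
            "blink_rate_hz", "gaze_noise_sd_deg", "press_latency_sd_s",
            "press_error_rate", "switch_hazard_per_s", "lapse_rate",
            "hold_through_iti_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rivalry_right_bias <= 1.0:
            raise ValueError("rivalry_right_bias must be in [0, 1]")

    @property
    def block_span_s(self) -> float:
        """Recorded span per block: pre-roll + 20 trials + a short tail."""
        per_trial = self.trial_s + self.iti_s
        return self.pre_roll_s + self.trials_per_block * per_trial + 0.5


@dataclass
class TrialTruth:
    block_index: int
    trial_index_in_block: int
    onset_s: float
    condition: Condition
    initial_dir: int
    switch_times_s: list[float] = field(default_factory=list)
    first_press_s: float | None = None
    lapse: bool = False
    press_error: bool = False
    hold_through_iti: bool = False


@dataclass
class GroundTruth:
    trials: list[TrialTruth] = field(default_factory=list)
    blink_intervals: list[tuple[int, float, float]] = field(default_factory=list)
    quickphase_times: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class SimulatedSession:
    session: Session
    truth: GroundTruth
    config: SimConfig

    def write(self, outdir, stem: str = "session") -> dict[str, Path]:
        """Emit gaze/buttons/events TSVs plus a YAML manifest recording the
        full config, so a run is reproducible from the manifest alone."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gaze = _concat_gaze([b.gaze for b in self.session.blocks])
        buttons = _concat_buttons([b.buttons for b in self.session.blocks])
        trials = [t for b in self.session.blocks for t in b.trials]
        paths = {
            "gaze": outdir / f"{stem}_gaze.tsv",
            "buttons": outdir / f"{stem}_buttons.tsv",
            "events": outdir / f"{stem}_events.tsv",
            "manifest": outdir / f"{stem}_manifest.yaml",
        }
        write_gaze(paths["gaze"], gaze)
        write_buttons(paths["buttons"], buttons)
        write_events(paths["events"], trials)
        manifest = {
            "subject_id": self.session.subject_id,
            "group": self.session.group.value,
            "state": self.session.state.value,
            "config": dataclasses.asdict(self.config),
        }
        paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
        return paths


def _concat_gaze(traces: list[GazeTrace]) -> GazeTrace:
    return GazeTrace(
        np.concatenate([t.time_s for t in traces]),
        np.concatenate([t.x_deg for t in traces]),
        np.concatenate([t.y_deg for t in traces]),
        np.concatenate([t.valid for t in traces]),
    )


def _concat_buttons(traces: list[ButtonTrace]) -> ButtonTrace:
    return ButtonTrace(
        np.concatenate([t.time_s for t in traces]),
        np.concatenate([t.raw_bp for t in traces]),
    )


def exemplar_button_trial(rate_hz: float = 60.0) -> ButtonTrace:
    """A canonical worked-example trial of raw button states.

    The subject briefly presses the left key starting at 0.5 s, corrects to a
    sustained right press, briefly releases just after 1 s, presses right
    again, and switches to left just before the 2-s trial ends.  The dominant
    label is right; the first press lands at 0.5 s and, because the smoothed
    ``BP`` must climb past +0.5 from under the preceding left press, the
    first *consistent* press lands at 0.6 s.
    """
    n = int(round(2.0 * rate_hz))
    t = np.arange(n) / rate_hz
    raw = np.zeros(n, dtype=int)
    raw[30:34] = -1   # brief left press at 0.5 s
    raw[34:62] = +1   # corrective right press, held
    raw[65:114] = +1  # right again after a brief release just after 1 s
    raw[114:] = -1    # left just before the end of the trial
    return ButtonTrace(time_s=t, raw_bp=raw)


def recommended_v_thresh(cfg: SimConfig) -> float:
    """Saccade-velocity threshold for analysing data from this generator:
    well above the slow-phase ceiling and sample-to-sample noise velocity,
    far below the single-sample quick-phase speed."""
    slow_ceiling = cfg.okn_gain * cfg.stim_speed_deg_s
    noise_v = cfg.gaze_noise_sd_deg * np.sqrt(2.0) * cfg.gaze_rate_hz / 2.0
    quick = cfg.quickphase_amplitude_deg * cfg.gaze_rate_hz
    lo = max(slow_ceiling * 2.0, noise_v * 8.0, 30.0)
    return float(min(max(lo, 100.0), quick / 4.0))


def _block_conditions(cfg: SimConfig, rng: np.random.Generator) -> list[Condition]:
    tpb = cfg.trials_per_block
    n_l = round(cfg.mix[0] * tpb)
    n_r = round(cfg.mix[1] * tpb)
    conds = (
        [Condition.NONRIV_LEFT] * n_l
        + [Condition.NONRIV_RIGHT] * n_r
        + [Condition.RIVALROUS] * (tpb - n_l - n_r)
    )
    return [conds[i] for i in rng.permutation(len(conds))]


def _percept_path(
    cfg: SimConfig, cond: Condition, rng: np.random.Generator
) -> tuple[int, list[float]]:
    """Initial dominant direction and within-trial switch times (relative to
    onset) of the latent percept."""
    if cond.rivalrous:
        initial = 1 if rng.random() < cfg.rivalry_right_bias else -1
        switches = []
        if cfg.switch_hazard_per_s > 0:
            t = rng.exponential(1.0 / cfg.switch_hazard_per_s)
            while t < cfg.trial_s:
                switches.append(float(t))
                t += rng.exponential(1.0 / cfg.switch_hazard_per_s)
        return initial, switches
    return cond.stim_dir, []


def _percept_dir_at(initial: int, switches: list[float], t: float) -> int:
    d = initial
    for sw in switches:
        if t >= sw:
            d = -d
    return d


def simulate_session(
    cfg: SimConfig,
    subject_id: str = "sim",
    group: Group = Group.CONTROL,
    state: SessionState = SessionState.NA,
) -> SimulatedSession:
    """Generate one full session (all blocks) with ground truth."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_blocks)
    session = Session(subject_id=subject_id, group=group, state=state)
    truth = GroundTruth()
    for b in range(cfg.n_blocks):
        rng = np.random.default_rng(streams[b])
        block, btruths, blinks, quicks = _simulate_block(cfg, b, rng)
        session.blocks.append(block)
        truth.trials.extend(btruths)
        truth.blink_intervals.extend(blinks)
        truth.quickphase_times.extend(quicks)
    return SimulatedSession(session=session, truth=truth, config=cfg)


def _simulate_block(cfg: SimConfig, b: int, rng: np.random.Generator):
    span = cfg.block_span_s
    t0 = b * span
    g_dt = 1.0 / cfg.gaze_rate_hz
    bt_dt = 1.0 / cfg.button_rate_hz
    n_g = int(round(span * cfg.gaze_rate_hz))
    n_bt = int(round(span * cfg.button_rate_hz))
    gt = t0 + np.arange(n_g) * g_dt
    bt = t0 + np.arange(n_bt) * bt_dt

    conds = _block_conditions(cfg, rng)
    per_trial = cfg.trial_s + cfg.iti_s
    onsets = t0 + cfg.pre_roll_s + np.arange(cfg.trials_per_block) * per_trial
    trials = [
        Trial(block_index=b, trial_index_in_block=k, onset_s=float(onsets[k]),
              condition=conds[k])
        for k in range(cfg.trials_per_block)
    ]

    truths = []
    v = np.zeros(n_g)  # latent slow-phase velocity
    for tr in trials:
        initial, switches = _percept_path(cfg, tr.condition, rng)
        truths.append(
            TrialTruth(
                block_index=b,
                trial_index_in_block=tr.trial_index_in_block,
                onset_s=tr.onset_s,
                condition=tr.condition,
                initial_dir=initial,
                switch_times_s=switches,
            )
        )
        # eye follows the percept with the oculomotor latency at onset and offset
        seg_edges = [0.0] + switches + [cfg.trial_s]
        for s0, s1 in zip(seg_edges[:-1], seg_edges[1:]):
            d = _percept_dir_at(initial, switches, (s0 + s1) / 2.0)
            i0 = np.searchsorted(gt, tr.onset_s + s0 + cfg.okn_latency_s)
            i1 = np.searchsorted(gt, tr.onset_s + s1 + cfg.okn_latency_s)
            v[i0:i1] = d * cfg.okn_gain * cfg.stim_speed_deg_s

    x = np.cumsum(v) * g_dt

    # quick phases: one-sample reset whenever |x| passes the trigger
    quicks: list[tuple[int, float]] = []
    i = 0
    while i < n_g:
        over = np.flatnonzero(np.abs(x[i:]) > cfg.quickphase_trigger_deg)
        if over.size == 0:
            break
        j = i + int(over[0])
        s = np.sign(x[j])
        x[j + 1:] -= s * cfg.quickphase_amplitude_deg
        quicks.append((b, float(gt[j])))
        i = j + 1

    valid = np.ones(n_g, dtype=bool)
    blinks: list[tuple[int, float, float]] = []
    if cfg.blink_rate_hz > 0:
        for _ in range(rng.poisson(cfg.blink_rate_hz * span)):
            start = t0 + rng.uniform(0.0, span)
            dur = max(3 * g_dt, rng.normal(cfg.blink_dur_mean_s, cfg.blink_dur_sd_s))
            i0 = np.searchsorted(gt, start)
            i1 = min(n_g, np.searchsorted(gt, start + dur))
            if i1 > i0:
                valid[i0:i1] = False
                blinks.append((b, float(gt[i0]), float(gt[i1 - 1] + g_dt)))

    x_obs = x + rng.normal(0.0, cfg.gaze_noise_sd_deg, n_g) if cfg.gaze_noise_sd_deg else x.copy()
    y_obs = rng.normal(0.0, cfg.gaze_noise_sd_deg, n_g) if cfg.gaze_noise_sd_deg else np.zeros(n_g)
    x_obs[~valid] = np.nan
    y_obs[~valid] = np.nan

    raw = np.zeros(n_bt, dtype=int)
    for tr, tru in zip(trials, truths):
        _simulate_buttons(cfg, rng, tr, tru, raw, bt)

    block = Block(
        index=b,
        gaze=GazeTrace(gt, x_obs, y_obs, valid),
        buttons=ButtonTrace(bt, raw),
        trials=trials,
    )
    return block, truths, blinks, quicks


def _simulate_buttons(cfg, rng, trial, truth, raw, bt) -> None:
    """Fill this trial's span of the block-level button array in place."""
    # draw the per-trial decisions in a fixed order so streams stay aligned
    lapse = rng.random() < cfg.lapse_rate
    err = rng.random() < cfg.press_error_rate
    hold = rng.random() < cfg.hold_through_iti_rate
    lat = max(1.0 / cfg.button_rate_hz,
              rng.normal(cfg.press_latency_mean_s, cfg.press_latency_sd_s))
    release_jitter = rng.uniform(0.15, 0.60)
    switch_lats = [
        max(1.0 / cfg.button_rate_hz,
            rng.normal(cfg.press_latency_mean_s, cfg.press_latency_sd_s))
        for _ in truth.switch_times_s
    ]

    if lapse or lat >= cfg.trial_s - 0.05:
        truth.lapse = True
        return
    truth.press_error = err
    truth.hold_through_iti = hold

    onset = trial.onset_s
    press_t = onset + lat
    if hold:
        # pressed through every ITI sample; released only after the ITI ends
        release_t = onset + cfg.trial_s + cfg.iti_s + 1.0 / cfg.button_rate_hz
    else:
        release_t = onset + cfg.trial_s + release_jitter

    # piecewise-constant key state from press to release
    changes: list[tuple[float, int]] = [(press_t, truth.initial_dir)]
    if err:
        changes = [
            (press_t, -truth.initial_dir),
            (press_t + cfg.press_error_dur_s, truth.initial_dir),
        ]
    for sw, sw_lat in zip(truth.switch_times_s, switch_lats):
        t_sw = onset + sw + sw_lat
        # a switch reported before the first press is folded into that press
        if press_t <= t_sw < min(release_t, onset + cfg.trial_s):
            d = _percept_dir_at(truth.initial_dir, truth.switch_times_s, sw)
            changes.append((t_sw, d))
    changes.sort(key=lambda c: c[0])

    bounds = [c[0] for c in changes] + [release_t]
    for (t_a, d), t_b in zip(changes, bounds[1:]):
        i0 = np.searchsorted(bt, t_a)
        i1 = np.searchsorted(bt, t_b)
        raw[i0:i1] = d

    i_first = np.searchsorted(bt, press_t)
    if i_first < len(bt):
        truth.first_press_s = float(bt[i_first] - onset)


def preset(group: str) -> SimConfig:
    """Documented parameter sets for the simulated study groups.

    ``CONTROL``, ``PD_ON`` (on treatment) and ``PD_OFF``: patients have a
    lower OKN gain (slower slow phases) and longer press latencies than
    controls, ordered OFF <= ON < CONTROL in gain and the reverse in
    latency.  Latency means follow the reported group means (0.482 s
    controls, 0.536 s patients on treatment); gains are set so the group
    gap in slow-phase speed is about 1.5 deg/s.
    """
    base = SimConfig()
    if group == "CONTROL":
        return base
    if group == "PD_ON":
        return dataclasses.replace(
            base, okn_gain=0.33, press_latency_mean_s=0.536, press_latency_sd_s=0.09
        )
    if group == "PD_OFF":
        return dataclasses.replace(
            base, okn_gain=0.30, press_latency_mean_s=0.560, press_latency_sd_s=0.10
        )
    raise ValueError(f"unknown preset {group!r} (CONTROL, PD_ON, PD_OFF)")
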