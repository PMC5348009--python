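import numpy as np
import pytest

from oknbr.session_io import ButtonTrace, GazeTrace
from oknbr.synthetic_data import SimConfig, STIM_SPEED_DEG_S

GAZE_RATE = 300.0
BUTTON_RATE = 60.0


def make_sawtooth(
    gain: float,
    direction: int,
    duration_s: float = 4.0,
    reset_period_s: float = 0.8,
    rate_hz: float = GAZE_RATE,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GazeTrace, float]:
    """Noise-free (by default) OKN-like sawtooth: constant slow-phase drift
    with a one-sample resetting jump every ``reset_period_s``.  Returns the
    trace and the true slow-phase velocity."""
    v = gain * STIM_SPEED_DEG_S * direction
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = v * t
    period = int(round(reset_period_s * rate_hz))
    amp = v * reset_period_s
    for j in range(period, n, period):
        x[j:] -= amp
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return GazeTrace(t, x, np.zeros(n), np.ones(n, bool)), v


def constant_buttons(
    value: int, duration_s: float = 3.0, rate_hz: float = BUTTON_RATE
) -> ButtonTrace:
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    return ButtonTrace(t, np.full(n, value, dtype=int))


@pytest.fixture
def noiseless_config() -> SimConfig:
    """Perfect responder: no noise, errors, lapses, switches or blinks."""
    return SimConfig(
        rng_seed=11,
        n_blocks=2,
        gaze_noise_sd_deg=0.0,
        blink_rate_hz=0.0,
        press_error_rate=0.0,
        lapse_rate=0.0,
        hold_through_iti_rate=0.0,
        switch_hazard_per_s=0.0,
        press_latency_sd_s=0.0,
    )
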