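"""Synthetic study protocols: simulated hypoxia challenges and an
experiment-like noisy dataset.

The hypoxia protocol drives the surrogate brain model with constant ABP
(100 mmHg) and PaCO2 (40 mmHg) while arterial saturation ramps from its
baseline (97%) down to a trough (65% by default) and back. The "healthy"
state uses default parameters; the "impaired" state changes exactly one
parameter, r_t = 0.013 cm, widening the muscular-tension curve (vessel
stiffening). The experiment-like generator emulates a measured adult hypoxia
challenge: repeated desaturation episodes to 80%, noisy blood pressure,
heavily quantised near-constant CO2, and observation noise on the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import get_model, simulate
from .timeseries import TimeSeriesSet

__all__ = ["ProtocolSpec", "gen_hypoxia_protocol", "gen_experiment_like", "IMPAIRED_RT"]

IMPAIRED_RT = 0.013  # cm; the single parameter change defining the impaired state


@dataclass(frozen=True)
class ProtocolSpec:
    """Specification of a synthetic protocol; a pure function of spec + seed."""

    state: str = "healthy"  # healthy | impaired | experiment_like
    duration: float = 1080.0  # s
    abp_baseline: float = 100.0  # mmHg
    paco2_baseline: float = 40.0  # mmHg
    sao2_baseline: float = 97.0  # %
    hypoxia_depth: float = 65.0  # % SaO2 at the trough
    n_episodes: int = 3
    noise_sd: dict[str, float] = field(default_factory=dict)  # per output channel
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.state not in ("healthy", "impaired", "experiment_like"):
            raise ValueError(f"unknown protocol state {self.state!r}")
        if not (0.0 <= self.hypoxia_depth <= self.sao2_baseline <= 100.0):
            raise ValueError("need 0 <= hypoxia_depth <= sao2_baseline <= 100")
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")


def _smooth_plateau(y: np.ndarray, width: int = 31, passes: int = 2) -> np.ndarray:
    """Round the corners of a piecewise-linear profile with repeated boxcar
    smoothing. Plateaus longer than the kernel keep their exact level, so
    the programmed trough value is attained exactly."""
    k = np.ones(width) / width
    for _ in range(passes):
        pad = width // 2
        yp = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        y = np.convolve(yp, k, mode="valid")
    return y


def _trapezoid(t: np.ndarray, start: float, down: float, hold: float, up: float,
               base: float, trough: float) -> np.ndarray:
    """Baseline -> linear fall -> hold -> linear recovery -> baseline."""
    y = np.full_like(t, base)
    t1, t2, t3, t4 = start, start + down, start + down + hold, start + down + hold + up
    falling = (t >= t1) & (t < t2)
    y[falling] = base + (trough - base) * (t[falling] - t1) / down
    y[(t >= t2) & (t < t3)] = trough
    rising = (t >= t3) & (t < t4)
    y[rising] = trough + (base - trough) * (t[rising] - t3) / up
    return y


def _theta_for_state(state: str) -> dict[str, float]:
    return {"r_t": IMPAIRED_RT} if state == "impaired" else {}


def _add_output_noise(outputs: TimeSeriesSet, noise_sd: dict[str, float], rng) -> TimeSeriesSet:
    if not noise_sd:
        return outputs
    channels = {}
    for name, y in outputs.channels.items():
        sd = noise_sd.get(name, 0.0)
        channels[name] = y + rng.normal(0.0, sd, size=y.size) if sd > 0 else y.copy()
    return TimeSeriesSet(outputs.t, channels, outputs.units)


def gen_hypoxia_protocol(spec: ProtocolSpec) -> tuple[TimeSeriesSet, TimeSeriesSet]:
    """Generate (inputs, outputs) for the simulated hypoxia challenge.

    ABP and PaCO2 are constant at their baselines; SaO2 follows a smoothed
    trapezoid from baseline to ``hypoxia_depth`` and back (default 300 s fall,
    300 s hold, 300 s recovery inside a 1080 s record). Outputs are the
    surrogate simulation at default parameters (healthy) or with r_t set to
    0.013 cm (impaired), plus optional seeded Gaussian observation noise.
    """
    if spec.state == "experiment_like":
        raise ValueError("use gen_experiment_like for the experiment-like protocol")
    t = np.arange(0.0, spec.duration, 1.0)
    seg = (spec.duration - 180.0) / 3.0  # 90 s lead-in/tail around fall/hold/recovery
    sao2 = _trapezoid(t, 90.0, seg, seg, seg, spec.sao2_baseline, spec.hypoxia_depth)
    sao2 = _smooth_plateau(sao2)
    inputs = TimeSeriesSet(
        t,
        {
            "ABP": np.full_like(t, spec.abp_baseline),
            "SaO2": sao2,
            "PaCO2": np.full_like(t, spec.paco2_baseline),
        },
        {"ABP": "mmHg", "SaO2": "%", "PaCO2": "mmHg"},
    )
    model = get_model("minibrain")
    outputs = simulate(model, _theta_for_state(spec.state), inputs)
    rng = np.random.default_rng(spec.seed)
    return inputs, _add_output_noise(outputs, spec.noise_sd, rng)


def gen_experiment_like(spec: ProtocolSpec) -> tuple[TimeSeriesSet, TimeSeriesSet]:
    """Generate a noisy, experiment-like (inputs, outputs) pair.

    SaO2 shows ``n_episodes`` (default 3) desaturation episodes to the
    programmed depth (80% is typical of a controlled adult hypoxia
    challenge); ABP is baseline plus band-limited noise; PaCO2 is
    near-constant and quantised to integer mmHg, emulating heavily quantised
    end-tidal CO2 readings. Outputs are the surrogate simulation plus
    per-channel Gaussian observation noise.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, 1.0)
    n = spec.n_episodes
    period = spec.duration / n
    fall = hold = rise = min(period / 5.0, 120.0)
    sao2 = np.full_like(t, spec.sao2_baseline)
    for i in range(n):
        start = i * period + (period - (fall + hold + rise)) / 2.0
        episode = _trapezoid(t, start, fall, hold, rise, spec.sao2_baseline, spec.hypoxia_depth)
        sao2 = np.minimum(sao2, episode)
    sao2 = _smooth_plateau(sao2, width=21)

    # band-limited ABP noise: white noise smoothed by a short boxcar cascade
    abp_noise = rng.normal(0.0, 3.0, size=t.size)
    abp = spec.abp_baseline + _smooth_plateau(abp_noise, width=15, passes=2)
    paco2 = np.round(spec.paco2_baseline + _smooth_plateau(rng.normal(0.0, 1.0, t.size), width=31))

    inputs = TimeSeriesSet(
        t,
        {"ABP": abp, "SaO2": sao2, "PaCO2": paco2},
        {"ABP": "mmHg", "SaO2": "%", "PaCO2": "mmHg"},
    )
    model = get_model("minibrain")
    clean = simulate(model, {}, inputs)
    noise = dict(spec.noise_sd)
    if not noise:
        # default: 2% of each channel's range
        noise = {
            name: 0.02 * float(np.ptp(y)) for name, y in clean.channels.items()
        }
    return inputs, _add_output_noise(clean, noise, rng)
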