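"""Toy test-function model y = a·x·sin(x) + b + ε.

A two-parameter closed-form "model" used to motivate and validate summary
statistics and the fitting machinery: parameter ``a`` controls sinusoidal
behaviour, ``b`` a constant offset, and ε is additive Gaussian noise. The x
grid spans one period, x_k = 2πk/n for k = 1..n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..timeseries import TimeSeriesSet
from .core import ModelDefinition, ParameterSpec

__all__ = ["ToyModelParams", "toy_simulate", "toy_model"]


@dataclass(frozen=True)
class ToyModelParams:
    a: float = 0.0
    b: float = 0.0
    noise_sd: float = 0.0
    n_points: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def toy_grid(n_points: int) -> np.ndarray:
    """x_k = 2πk/n, k = 1..n — one full period, endpoint included."""
    return 2.0 * np.pi * np.arange(1, n_points + 1) / n_points


def toy_simulate(params: ToyModelParams) -> TimeSeriesSet:
    """Evaluate y = a·x·sin(x) + b + ε on the one-period grid.

    ε ~ N(0, noise_sd²) i.i.d., reproducible for a fixed seed. The x grid is
    stored as the time axis of the returned TimeSeriesSet.
    """
    x = toy_grid(params.n_points)
    y = params.a * x * np.sin(x) + params.b
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        y = y + rng.normal(0.0, params.noise_sd, size=x.size)
    return TimeSeriesSet(x, {"y": y})


def _toy_outputs(t, Y, theta, U):
    return {"y": theta["a"] * t * np.sin(t) + theta["b"]}


def _toy_outputs_batch(t, traj, theta, U):
    # (B, n_t): closed form, no state dependence
    return {"y": theta["a"][:, None] * (t * np.sin(t))[None, :] + theta["b"][:, None]}


def toy_model() -> ModelDefinition:
    """The toy function wrapped as a (stateless) ModelDefinition.

    It declares a single inert state with zero dynamics so it can flow through
    the same simulate/fit machinery as the physiological models; outputs are
    the closed form evaluated on the time grid (noise-free).
    """
    return ModelDefinition(
        name="toy",
        state_names=["s"],
        differential_flags=[True],
        rhs=lambda t, y, theta, u: np.zeros(1),
        input_names=[],
        output_names=["y"],
        outputs=_toy_outputs,
        parameter_table={
            "a": ParameterSpec("a", 0.0, "", "amplitude of the x·sin(x) component"),
            "b": ParameterSpec("b", 0.0, "", "constant offset"),
        },
        delta_outputs=set(),
        initial_guess=lambda theta, u0: np.zeros(1),
        rhs_batch=lambda t, Y, theta, u: np.zeros_like(Y),
        outputs_batch=_toy_outputs_batch,
        steady_state_batch=lambda theta, u0: np.zeros((1, len(next(iter(theta.values()))))),
    )
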