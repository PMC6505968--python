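"""Model container and integration for differential-algebraic systems.

A model is the DAE  M·dy/dt = f(y, θ, t)  with a diagonal 0/1 mass matrix:
states whose mass-matrix row is zero are algebraic and their component of
``f`` is a residual to be solved, not integrated. Algebraic states are
handled by nested root solves inside the right-hand side (equivalent to a
mass-matrix integrator at these problem scales, and much simpler).

Simulation always starts from the steady state implied by the inputs at t=0,
so that Δ-outputs (concentration changes) are exactly zero at the start of a
record, matching how NIRS changes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from ..timeseries import TimeSeriesSet, normalise_delta

__all__ = ["ParameterSpec", "ModelDefinition", "simulate", "steady_state", "SimulationError"]


class SimulationError(RuntimeError):
    """Raised when integration fails or produces non-finite states."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: default value, optional hard bounds, unit, meaning."""

    name: str
    default: float
    unit: str = ""
    doc: str = ""
    lower: float | None = None
    upper: float | None = None


@dataclass
class ModelDefinition:
    """A named DAE model with declared inputs, outputs and parameters.

    ``rhs(t, y, theta, u)`` returns, per state, the time derivative
    (differential states) or the algebraic residual (algebraic states);
    ``theta`` is a dict of parameter values, ``u`` the input vector at time t
    in the order of ``input_names``.

    ``outputs(t, Y, theta, U)`` maps a state trajectory (n_states × n_t) and
    input trajectory (n_inputs × n_t) to a dict of output series. Outputs
    listed in ``delta_outputs`` are reported as changes and are normalised to
    start at exactly 0.

    Vectorised models may provide ``rhs_batch``/``outputs_batch``/
    ``steady_state_batch`` operating on (n_states, B) state arrays with
    parameter dicts of length-B arrays; the rejection sampler uses these for
    whole-batch simulation.
    """

    name: str
    state_names: list[str]
    differential_flags: list[bool]
    rhs: Callable
    input_names: list[str]
    output_names: list[str]
    outputs: Callable
    parameter_table: dict[str, ParameterSpec]
    delta_outputs: set[str] = field(default_factory=set)
    initial_guess: Callable | None = None  # (theta, u0) -> state vector
    steady_solver: Callable | None = None  # (theta, u0) -> state vector, model-specific
    rhs_batch: Callable | None = None
    outputs_batch: Callable | None = None
    steady_state_batch: Callable | None = None
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.differential_flags) != len(self.state_names):
            raise ValueError("differential_flags length must equal state count")

    def default_theta(self) -> dict[str, float]:
        return {k: spec.default for k, spec in self.parameter_table.items()}

    def complete_theta(self, theta: dict[str, float] | None) -> dict[str, float]:
        """Fill unspecified parameters with defaults; reject unknown names."""
        full = self.default_theta()
        if theta:
            unknown = set(theta) - set(full)
            if unknown:
                raise KeyError(f"unknown parameters for model {self.name!r}: {sorted(unknown)}")
            full.update(theta)
        return full


def steady_state(
    model: ModelDefinition,
    theta: dict[str, float] | None,
    const_inputs: dict[str, float],
    tol: float = 1e-8,
) -> np.ndarray:
    """Solve f(y, θ, t=0) = 0 for constant inputs.

    Uses the model's own steady solver when it provides one (e.g. a bracketed
    scalar solve), otherwise a damped Newton/hybrid root find from the model's
    initial guess. The residual norm at the returned state is checked against
    ``tol``.
    """
    theta = model.complete_theta(theta)
    u0 = np.array([const_inputs[n] for n in model.input_names], dtype=float)
    if model.steady_solver is not None:
        y0 = np.asarray(model.steady_solver(theta, u0), dtype=float)
    else:
        guess = (
            np.asarray(model.initial_guess(theta, u0), dtype=float)
            if model.initial_guess is not None
            else np.zeros(len(model.state_names))
        )
        sol = root(lambda y: np.asarray(model.rhs(0.0, y, theta, u0), dtype=float), guess, method="hybr")
        if not sol.success:
            raise SimulationError(f"steady-state solve failed for {model.name!r}: {sol.message}")
        y0 = sol.x
    res = np.linalg.norm(np.asarray(model.rhs(0.0, y0, theta, u0), dtype=float))
    if not np.isfinite(res) or res > tol:
        raise SimulationError(
            f"steady-state residual {res:.3g} exceeds tolerance {tol:.3g} for {model.name!r}"
        )
    return y0


def _make_ode_rhs(model: ModelDefinition, theta, input_fn):
    """Reduce the DAE to an ODE on the differential states.

    Algebraic states are re-solved at every rhs evaluation, warm-started from
    the previous solution.
    """
    flags = np.asarray(model.differential_flags, dtype=bool)
    n = len(flags)
    if flags.all():
        def rhs(t, y):
            return np.asarray(model.rhs(t, y, theta, input_fn(t)), dtype=float)

        return rhs, flags

    idx_d = np.where(flags)[0]
    idx_a = np.where(~flags)[0]
    last_alg = {"v": None}

    def assemble(y_d, y_a):
        y = np.empty(n)
        y[idx_d] = y_d
        y[idx_a] = y_a
        return y

    def rhs(t, y_d):
        u = input_fn(t)
        guess = last_alg["v"] if last_alg["v"] is not None else np.zeros(idx_a.size)

        def alg_res(y_a):
            return np.asarray(model.rhs(t, assemble(y_d, y_a), theta, u), dtype=float)[idx_a]

        sol = root(alg_res, guess, method="hybr")
        if not sol.success:
            raise SimulationError(f"algebraic solve failed at t={t:.3f} for {model.name!r}")
        last_alg["v"] = sol.x
        full = np.asarray(model.rhs(t, assemble(y_d, sol.x), theta, u), dtype=float)
        return full[idx_d]

    return rhs, flags


def simulate(
    model: ModelDefinition,
    theta: dict[str, float] | None,
    inputs: TimeSeriesSet,
    t_grid: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "Radau",
) -> TimeSeriesSet:
    """Integrate a model over the input record and return its output channels.

    The initial state is the steady state at the t=0 input values, so constant
    inputs produce constant outputs and Δ-outputs start at 0. Tolerances map
    directly onto the stiff-capable scipy integrator.
    """
    theta = model.complete_theta(theta)
    missing = [n for n in model.input_names if n not in inputs]
    if missing:
        raise KeyError(f"missing input channel(s) {missing} for model {model.name!r}")
    if t_grid is None:
        t_grid = inputs.t
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < inputs.t[0] - 1e-9 or t_grid[-1] > inputs.t[-1] + 1e-9:
        raise ValueError("t_grid extends beyond the input record")

    input_fn = inputs.interpolator(model.input_names)
    u0 = {n: float(inputs[n][0]) for n in model.input_names}
    y0 = steady_state(model, theta, u0)

    flags = np.asarray(model.differential_flags, dtype=bool)
    rhs, flags = _make_ode_rhs(model, theta, input_fn)
    y0_d = y0[flags]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0_d,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed for {model.name!r}: {sol.message}")
    Y = np.empty((len(model.state_names), t_grid.size))
    Y[flags] = sol.y
    if not flags.all():
        # recover algebraic states pointwise along the returned grid
        idx_a = np.where(~flags)[0]
        guess = y0[idx_a]
        for j, tj in enumerate(t_grid):
            u = input_fn(tj)

            def alg_res(y_a, _j=j, _t=tj, _u=u):
                y = Y[:, _j].copy()
                y[idx_a] = y_a
                return np.asarray(model.rhs(_t, y, theta, _u), dtype=float)[idx_a]

            r = root(alg_res, guess, method="hybr")
            Y[idx_a, j] = r.x
            guess = r.x
    bad = ~np.isfinite(Y)
    if bad.any():
        i_state = int(np.argwhere(bad.any(axis=1))[0])
        raise SimulationError(
            f"non-finite state {model.state_names[i_state]!r} in {model.name!r} simulation"
        )

    if model.input_names:
        U = np.vstack([np.interp(t_grid, inputs.t, inputs[n]) for n in model.input_names])
    else:
        U = np.empty((0, t_grid.size))
    out = model.outputs(t_grid, Y, theta, U)
    channels = {}
    for name in model.output_names:
        y = np.asarray(out[name], dtype=float)
        channels[name] = normalise_delta(y) if name in model.delta_outputs else y
    return TimeSeriesSet(t_grid, channels, dict(model.units))


def simulate_batch(
    model: ModelDefinition,
    thetas: dict[str, np.ndarray],
    inputs: TimeSeriesSet,
    n_substeps: int = 2,
) -> dict[str, np.ndarray]:
    """Fixed-step RK4 simulation of many parameter vectors at once.

    ``thetas`` maps parameter name -> length-B array (unlisted parameters use
    defaults). Returns output name -> (B, n_t) array, Δ-outputs normalised.
    Requires the model to provide the vectorised hooks; accuracy relative to
    the adaptive path is validated in the test-suite for the bundled models.
    """
    if model.rhs_batch is None or model.steady_state_batch is None or model.outputs_batch is None:
        raise NotImplementedError(f"model {model.name!r} has no vectorised batch interface")
    B = len(next(iter(thetas.values())))
    full = {k: np.full(B, spec.default, dtype=float) for k, spec in model.parameter_table.items()}
    for k, v in thetas.items():
        if k not in full:
            raise KeyError(f"unknown parameter {k!r} for model {model.name!r}")
        full[k] = np.asarray(v, dtype=float)

    t = inputs.t
    if model.input_names:
        U = np.vstack([inputs[n] for n in model.input_names])
    else:
        U = np.empty((0, t.size))
    Y = model.steady_state_batch(full, U[:, 0])  # (n_states, B)
    n_t = t.size
    traj = np.empty((Y.shape[0], B, n_t))
    traj[:, :, 0] = Y
    for j in range(n_t - 1):
        h = (t[j + 1] - t[j]) / n_substeps
        for s in range(n_substeps):
            ts = t[j] + s * h
            frac0 = (ts - t[j]) / (t[j + 1] - t[j])
            frac1 = (ts + h - t[j]) / (t[j + 1] - t[j])
            u0 = U[:, j] * (1 - frac0) + U[:, j + 1] * frac0
            um = U[:, j] * (1 - (frac0 + frac1) / 2) + U[:, j + 1] * (frac0 + frac1) / 2
            u1 = U[:, j] * (1 - frac1) + U[:, j + 1] * frac1
            k1 = model.rhs_batch(ts, Y, full, u0)
            k2 = model.rhs_batch(ts + h / 2, Y + h / 2 * k1, full, um)
            k3 = model.rhs_batch(ts + h / 2, Y + h / 2 * k2, full, um)
            k4 = model.rhs_batch(ts + h, Y + h * k3, full, u1)
            Y = Y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[:, :, j + 1] = Y

    out = model.outputs_batch(t, traj, full, U)  # name -> (B, n_t)
    result = {}
    for name in model.output_names:
        y = out[name]
        if name in model.delta_outputs:
            y = y - y[:, :1]
        result[name] = y
    return result
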