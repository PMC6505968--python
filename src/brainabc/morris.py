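"""Morris elementary-effects screening with SBTP summaries.

One-at-a-time trajectories over parameter ranges of default ±50% (the
standard screening range for these models). For each parameter the method
reports μ* — the mean absolute elementary effect, used for ranking — and σ,
the standard deviation of the effects (a non-linearity indicator, reported
but never used for selection). Effects are computed in unit-scaled [0, 1]
parameter space so that μ* is comparable across parameters with different
units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import sbtp
from .models import ModelDefinition, simulate_batch
from .timeseries import TimeSeriesSet

__all__ = [
    "MorrisDesign",
    "SensitivityResult",
    "make_ranges",
    "morris_design",
    "elementary_effects",
    "joint_summary",
    "rank_top",
    "run_morris",
]


def make_ranges(defaults: dict[str, float], fraction: float = 0.5) -> dict[str, tuple[float, float]]:
    """Per-parameter bounds (default·(1−fraction), default·(1+fraction)).

    A zero default gives a degenerate range and is rejected; such parameters
    need explicit bounds.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    out = {}
    for name, d in defaults.items():
        if d == 0:
            raise ValueError(f"parameter {name!r} has default 0; give explicit bounds")
        lo, hi = d * (1 - fraction), d * (1 + fraction)
        out[name] = (min(lo, hi), max(lo, hi))
    return out


@dataclass
class MorrisDesign:
    """A trajectory design: r·(k+1) rows of parameter vectors."""

    names: list[str]
    bounds: dict[str, tuple[float, float]]
    matrix: np.ndarray       # (rows, k) physical units
    unit_matrix: np.ndarray  # (rows, k) in [0, 1]
    trajectory_index: np.ndarray  # (rows,)
    levels: int
    delta: float

    @property
    def n_trajectories(self) -> int:
        return int(self.trajectory_index[-1]) + 1


def morris_design(
    bounds: dict[str, tuple[float, float]],
    n_trajectories: int = 50,
    levels: int = 4,
    seed: int | None = None,
) -> MorrisDesign:
    """Random one-at-a-time trajectory design on a ``levels``-level grid.

    Each trajectory starts at a random grid point and perturbs every
    parameter exactly once, in random order and random direction, by
    Δ = levels / (2·(levels − 1)) in unit space. Consecutive rows within a
    trajectory therefore differ in exactly one coordinate.
    """
    if levels < 4 or levels % 2:
        raise ValueError("levels must be an even integer >= 4")
    if n_trajectories < 2:
        raise ValueError("need at least 2 trajectories")
    names = list(bounds)
    k = len(names)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    if np.any(hi <= lo):
        raise ValueError("every bound must satisfy lower < upper")
    delta = levels / (2.0 * (levels - 1))
    rng = np.random.default_rng(seed)
    base_levels = np.arange(levels // 2) / (levels - 1)  # grid points with x + delta <= 1

    rows_u, traj_idx = [], []
    for tr in range(n_trajectories):
        x = rng.choice(base_levels, size=k)
        direction = rng.choice([-1.0, 1.0], size=k)
        # flip directions that would leave [0, 1]
        up_ok = x + delta <= 1.0 + 1e-12
        down_ok = x - delta >= -1e-12
        direction = np.where((direction > 0) & ~up_ok, -1.0, direction)
        direction = np.where((direction < 0) & ~down_ok, 1.0, direction)
        order = rng.permutation(k)
        rows_u.append(x.copy())
        traj_idx.append(tr)
        for j in order:
            x = x.copy()
            x[j] = x[j] + direction[j] * delta
            rows_u.append(x)
            traj_idx.append(tr)
    U = np.asarray(rows_u)
    M = lo + U * (hi - lo)
    return MorrisDesign(names, dict(bounds), M, U, np.asarray(traj_idx), levels, delta)


@dataclass
class SensitivityResult:
    """μ*/σ per parameter for one or more responses."""

    names: list[str]
    mu_star: dict[str, dict[str, float]]  # response -> param -> mu*
    sigma: dict[str, dict[str, float]]
    n_trajectories_used: int
    n_trajectories_dropped: int = 0

    def ranking(self, response: str = "joint") -> list[str]:
        return rank_top(self, n=len(self.names), response=response)


def _effects_one(design: MorrisDesign, response: np.ndarray) -> tuple[dict[str, float], dict[str, float], int, int]:
    k = len(design.names)
    per_param: dict[int, list[float]] = {j: [] for j in range(k)}
    n_used = n_dropped = 0
    for tr in range(design.n_trajectories):
        sel = design.trajectory_index == tr
        U = design.unit_matrix[sel]
        resp = response[sel]
        if not np.all(np.isfinite(resp)):
            n_dropped += 1
            continue
        n_used += 1
        for i in range(U.shape[0] - 1):
            du = U[i + 1] - U[i]
            j = int(np.argmax(np.abs(du)))
            step = du[j]
            per_param[j].append((resp[i + 1] - resp[i]) / step)
    mu_star, sigma = {}, {}
    for j, name in enumerate(design.names):
        ee = np.asarray(per_param[j])
        if ee.size == 0:
            mu_star[name], sigma[name] = np.nan, np.nan
        else:
            mu_star[name] = float(np.mean(np.abs(ee)))
            sigma[name] = float(np.std(ee, ddof=1)) if ee.size > 1 else 0.0
    return mu_star, sigma, n_used, n_dropped


def elementary_effects(
    design: MorrisDesign,
    responses: np.ndarray | dict[str, np.ndarray],
) -> SensitivityResult:
    """Compute μ* and σ from per-row responses.

    ``responses`` is either a single array (one scalar per design row) or a
    dict of named response arrays (e.g. one per model output, plus 'joint').
    Trajectories containing non-finite responses are dropped whole so that
    effect pairing stays valid; the drop count is reported.
    """
    if not isinstance(responses, dict):
        responses = {"response": np.asarray(responses, dtype=float)}
    n_rows = design.matrix.shape[0]
    for key, r in responses.items():
        if len(r) != n_rows:
            raise ValueError(f"response {key!r} has {len(r)} values for {n_rows} design rows")
    mu_star, sigma = {}, {}
    n_used = n_dropped = 0
    for key, r in responses.items():
        m, s, n_used, n_dropped = _effects_one(design, np.asarray(r, dtype=float))
        mu_star[key], sigma[key] = m, s
    return SensitivityResult(design.names, mu_star, sigma, n_used, n_dropped)


def joint_summary(per_output: dict[str, np.ndarray]) -> np.ndarray:
    """Row-wise sum of per-output summary values (the joint SBTP response)."""
    arrays = [np.asarray(v, dtype=float) for v in per_output.values()]
    n = {a.shape for a in arrays}
    if len(n) != 1:
        raise ValueError("per-output summaries must share the same shape")
    return np.sum(arrays, axis=0)


def rank_top(result: SensitivityResult, n: int = 10, response: str | None = None) -> list[str]:
    """The n parameters with the highest μ*, descending.

    Exact ties are broken by declaration order in the design.
    """
    if response is None:
        response = "joint" if "joint" in result.mu_star else next(iter(result.mu_star))
    mu = result.mu_star[response]
    if n > len(result.names):
        raise ValueError(f"asked for top {n} of {len(result.names)} parameters")
    order = sorted(range(len(result.names)), key=lambda i: (-mu[result.names[i]], i))
    return [result.names[i] for i in order[:n]]


def run_morris(
    model: ModelDefinition,
    inputs: TimeSeriesSet,
    parameters: list[str] | None = None,
    outputs: list[str] | None = None,
    n_trajectories: int = 50,
    levels: int = 4,
    fraction: float = 0.5,
    seed: int | None = None,
    n_substeps: int = 2,
) -> tuple[SensitivityResult, MorrisDesign]:
    """Screen a model over a protocol: SBTP response per output and jointly.

    The reference range for each output's SBTP scaling is taken from the
    default-parameter simulation of the same protocol. Simulation of all
    design rows uses the vectorised batch path.
    """
    parameters = parameters or [
        n for n in model.parameter_table if model.parameter_table[n].default != 0
    ]
    outputs = outputs or model.output_names
    defaults = {n: model.parameter_table[n].default for n in parameters}
    design = morris_design(make_ranges(defaults, fraction), n_trajectories, levels, seed)

    ref = simulate_batch(
        model, {parameters[0]: np.array([defaults[parameters[0]]])}, inputs, n_substeps
    )
    ref_range = {}
    for out in outputs:
        rng_ = float(np.ptp(ref[out][0]))
        if rng_ <= 0:
            raise ValueError(f"default run of output {out!r} is flat; SBTP scale undefined")
        ref_range[out] = rng_

    thetas = {name: design.matrix[:, j] for j, name in enumerate(design.names)}
    sims = simulate_batch(model, thetas, inputs, n_substeps)
    responses: dict[str, np.ndarray] = {}
    for out in outputs:
        Y = sims[out]
        with np.errstate(invalid="ignore"):
            vals = np.array([sbtp(Y[i], ref_range[out]) if np.all(np.isfinite(Y[i])) else np.nan
                             for i in range(Y.shape[0])])
        responses[out] = vals
    responses["joint"] = joint_summary({k: responses[k] for k in outputs})
    return elementary_effects(design, responses), design
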