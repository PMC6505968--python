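"""Likelihood-free rejection fitting.

Draw parameter vectors from uniform priors, simulate the model for every
draw, measure a multi-channel distance between simulation and observation,
and keep either all draws within a tolerance ε or the fixed fraction of
draws with the smallest distances (fixed acceptance rate). The accepted
draws with their distances approximate the posterior p(θ | d(y, y_rep) ≤ ε).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distances import DISTANCE_KINDS
from .models import ModelDefinition, simulate, simulate_batch
from .timeseries import TimeSeriesSet, normalise_delta

__all__ = [
    "PriorSet",
    "BatchResult",
    "Posterior",
    "TopKSelector",
    "sample_prior",
    "run_batch",
    "accept_by_rate",
    "accept_by_tolerance",
    "fit",
]


@dataclass(frozen=True)
class PriorSet:
    """Independent uniform priors over the fitted parameters.

    ``bounds`` maps parameter name -> (lower, upper); parameters not listed
    stay pinned at their model defaults during fitting.
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (lo < hi):
                raise ValueError(f"prior for {name!r} needs lower < upper, got ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)


def sample_prior(priors: PriorSet, n: int, seed=None) -> dict[str, np.ndarray]:
    """n independent uniform draws per parameter, reproducible under seed.

    ``seed`` may be an int or a numpy Generator/SeedSequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {
        name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in priors.bounds.items()
    }


@dataclass
class BatchResult:
    """Draws and distances from one simulation batch."""

    draws: dict[str, np.ndarray]
    distances: np.ndarray                 # combined distance; inf for failed draws
    per_channel: dict[str, np.ndarray]
    n_failed: int
    seed: object = None
    batch_index: int = 0

    @property
    def n(self) -> int:
        return self.distances.size


def _observed_channels(observed: TimeSeriesSet, channels: list[str], model: ModelDefinition):
    obs = {}
    for ch in channels:
        if ch not in observed:
            raise KeyError(f"observed data lacks fitted channel {ch!r}")
        y = observed[ch]
        obs[ch] = normalise_delta(y) if ch in model.delta_outputs else np.asarray(y, float)
    return obs


def run_batch(
    model: ModelDefinition,
    priors: PriorSet,
    observed: TimeSeriesSet,
    channels: list[str],
    n: int,
    seed=None,
    kind: str = "nrmse",
    weights: dict[str, float] | None = None,
    batch_index: int = 0,
    n_substeps: int = 2,
    chunk: int = 5000,
) -> BatchResult:
    """Simulate ``n`` prior draws against an observed record.

    The observed set must contain the model input channels and every fitted
    output channel. Simulations producing non-finite outputs are recorded as
    failures (distance = +inf, never acceptable) rather than dropped; more
    than 50% failures aborts with a diagnostic. Identical seeds give
    identical results.
    """
    if kind not in DISTANCE_KINDS:
        raise ValueError(f"unknown distance kind {kind!r}")
    missing = [c for c in model.input_names if c not in observed]
    if missing:
        raise KeyError(f"observed data lacks model input channel(s) {missing}")
    obs = _observed_channels(observed, channels, model)
    ranges = {}
    for ch, y in obs.items():
        rng_ = float(np.ptp(y))
        if kind == "nrmse" and rng_ <= 0:
            raise ValueError(f"observed channel {ch!r} is flat; NRMSE undefined")
        ranges[ch] = rng_

    draws = sample_prior(priors, n, seed)
    distances = np.empty(n)
    per_channel = {ch: np.empty(n) for ch in channels}
    w = {ch: (weights.get(ch, 1.0) if weights else 1.0) for ch in channels}

    use_batch = model.rhs_batch is not None
    dist_fn = DISTANCE_KINDS[kind]
    for start in range(0, n, chunk if use_batch else 1):
        stop = min(start + chunk, n) if use_batch else start + 1
        theta_chunk = {k: v[start:stop] for k, v in draws.items()}
        if use_batch:
            sims = simulate_batch(model, theta_chunk, observed, n_substeps)
            total = np.zeros(stop - start)
            bad = np.zeros(stop - start, dtype=bool)
            for ch in channels:
                Y = sims[ch]
                bad |= ~np.all(np.isfinite(Y), axis=1)
                if kind == "nrmse":
                    d = np.sqrt(np.mean((Y - obs[ch][None, :]) ** 2, axis=1)) / ranges[ch]
                elif kind == "rmse":
                    d = np.sqrt(np.mean((Y - obs[ch][None, :]) ** 2, axis=1))
                elif kind == "euclidean":
                    d = np.sqrt(np.sum((Y - obs[ch][None, :]) ** 2, axis=1))
                else:  # sbtp
                    d = np.array([dist_fn(obs[ch], Y[i]) for i in range(Y.shape[0])])
                per_channel[ch][start:stop] = d
                total += w[ch] * d
            total = np.where(bad, np.inf, total)
            distances[start:stop] = total
        else:
            theta = {k: float(v[0]) for k, v in theta_chunk.items()}
            try:
                sim = simulate(model, theta, observed)
                total = 0.0
                for ch in channels:
                    d = dist_fn(obs[ch], sim[ch])
                    per_channel[ch][start] = d
                    total += w[ch] * d
                distances[start] = total
            except Exception:
                distances[start] = np.inf
                for ch in channels:
                    per_channel[ch][start] = np.nan

    n_failed = int(np.sum(~np.isfinite(distances)))
    if n_failed > n / 2:
        raise RuntimeError(
            f"{n_failed}/{n} simulations failed; check priors/model before fitting"
        )
    return BatchResult(draws, distances, per_channel, n_failed, seed, batch_index)


@dataclass
class Posterior:
    """Accepted draws with their distances plus acceptance metadata."""

    draws: dict[str, np.ndarray]
    distances: np.ndarray
    per_channel: dict[str, np.ndarray]
    rule: dict
    n_simulated: int
    n_accepted: int
    distance_min: float
    distance_max: float

    def median(self) -> dict[str, float]:
        return {k: float(np.median(v)) for k, v in self.draws.items()}


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


class TopKSelector:
    """Streaming selection of the k smallest-distance draws across batches.

    Memory is bounded by k + one batch. Ties at the cutoff keep the
    first-seen draw (stable ordering by arrival), so results are
    deterministic and identical to a full stable sort of all draws.
    """

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._dist = np.empty(0)
        self._order = np.empty(0, dtype=np.int64)  # arrival index, for stable ties
        self._draws: dict[str, np.ndarray] | None = None
        self._per_channel: dict[str, np.ndarray] | None = None
        self._seen = 0

    def update(self, distances, draws: dict[str, np.ndarray], per_channel: dict[str, np.ndarray] | None = None):
        distances = np.asarray(distances, dtype=float)
        n = distances.size
        arrival = np.arange(self._seen, self._seen + n, dtype=np.int64)
        self._seen += n
        per_channel = per_channel or {}
        if self._draws is None:
            self._draws = {k: np.asarray(v, float) for k, v in draws.items()}
            self._per_channel = {k: np.asarray(v, float) for k, v in per_channel.items()}
            cat_d, cat_o = distances, arrival
        else:
            cat_d = np.concatenate([self._dist, distances])
            cat_o = np.concatenate([self._order, arrival])
            self._draws = {k: np.concatenate([self._draws[k], np.asarray(v, float)]) for k, v in draws.items()}
            self._per_channel = {
                k: np.concatenate([self._per_channel[k], np.asarray(v, float)])
                for k, v in per_channel.items()
            }
        sel = np.lexsort((cat_o, cat_d))[: self.k]
        self._dist = cat_d[sel]
        self._order = cat_o[sel]
        self._draws = {k: v[sel] for k, v in self._draws.items()}
        self._per_channel = {k: v[sel] for k, v in self._per_channel.items()}

    def result(self):
        resel = np.argsort(self._order, kind="stable")  # arrival order within the top-k
        return (
            self._dist[resel],
            {k: v[resel] for k, v in self._draws.items()},
            {k: v[resel] for k, v in (self._per_channel or {}).items()},
            self._seen,
        )


def _as_batches(batches) -> list[BatchResult]:
    return [batches] if isinstance(batches, BatchResult) else list(batches)


def accept_by_rate(batches, rate: float) -> Posterior:
    """Keep the fraction ``rate`` of draws with the lowest distances.

    The number accepted is rate·N rounded half away from zero, over the total
    N of all batches (failed simulations count towards N but can never be
    accepted). Raises if rate·N rounds below 1.
    """
    if not (0.0 < rate <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    batches = _as_batches(batches)
    N = sum(b.n for b in batches)
    k = _round_half_away(rate * N)
    if k < 1:
        raise ValueError(
            f"rate {rate} of {N} draws accepts none; run more simulations"
        )
    sel = TopKSelector(k)
    for b in batches:
        sel.update(b.distances, b.draws, b.per_channel)
    dist, draws, per_ch, seen = sel.result()
    finite = np.isfinite(dist)
    if not finite.all():
        raise RuntimeError("acceptance rate exceeds the number of successful simulations")
    return Posterior(
        draws, dist, per_ch,
        {"kind": "rate", "rate": rate},
        N, k, float(dist.min()), float(dist.max()),
    )


def accept_by_tolerance(batches, epsilon: float) -> Posterior:
    """Keep every draw with distance ≤ ε (the textbook rejection rule)."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    batches = _as_batches(batches)
    N = sum(b.n for b in batches)
    keep_d, keep_draws, keep_pc = [], [], []
    for b in batches:
        m = b.distances <= epsilon
        keep_d.append(b.distances[m])
        keep_draws.append({k: v[m] for k, v in b.draws.items()})
        keep_pc.append({k: v[m] for k, v in b.per_channel.items()})
    dist = np.concatenate(keep_d) if keep_d else np.empty(0)
    names = batches[0].draws.keys()
    draws = {k: np.concatenate([d[k] for d in keep_draws]) for k in names}
    per_ch = {k: np.concatenate([p[k] for p in keep_pc]) for k in batches[0].per_channel}
    if dist.size == 0:
        warnings.warn(f"no draws within tolerance {epsilon}; posterior is empty", stacklevel=2)
    return Posterior(
        draws, dist, per_ch,
        {"kind": "tolerance", "epsilon": epsilon},
        N, int(dist.size),
        float(dist.min()) if dist.size else np.nan,
        float(dist.max()) if dist.size else np.nan,
    )


def fit(
    model: ModelDefinition,
    observed: TimeSeriesSet,
    priors: PriorSet,
    channels: list[str],
    n: int,
    seed: int,
    batch_size: int = 100000,
    rate: float | None = 1e-4,
    epsilon: float | None = None,
    kind: str = "nrmse",
    weights: dict[str, float] | None = None,
    n_substeps: int = 2,
) -> Posterior:
    """End-to-end rejection fit: batched simulation then acceptance.

    One master seed spawns an independent RNG stream per batch, so the result
    is reproducible for a fixed (seed, n, batch_size) triple.
    """
    if (rate is None) == (epsilon is None):
        raise ValueError("give exactly one of rate or epsilon")
    ss = np.random.SeedSequence(seed)
    n_batches = int(np.ceil(n / batch_size))
    streams = ss.spawn(n_batches)
    batches = []
    done = 0
    for i in range(n_batches):
        m = min(batch_size, n - done)
        done += m
        batches.append(
            run_batch(
                model, priors, observed, channels, m,
                seed=np.random.default_rng(streams[i]), kind=kind,
                weights=weights, batch_index=i, n_substeps=n_substeps,
            )
        )
    if rate is not None:
        return accept_by_rate(batches, rate)
    return accept_by_tolerance(batches, epsilon)
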