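"""Posterior predictive distribution and model-checking statistics.

After a rejection fit, parameter draws are resampled from the posterior
(25 draws by default, with replacement), the model is simulated for each,
and the simulations are aggregated pointwise into a median trace and a
central credible band. The fit is then checked channel by channel:
autocorrelation of observed vs predicted, residual distribution (mean, SD,
histogram) with Q-Q points against the normal, and per-parameter
Kullback-Leibler divergence from prior to posterior, quantifying how much
information the data provided about each parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .models import ModelDefinition, simulate_batch
from .rejection import Posterior, PriorSet
from .timeseries import TimeSeriesSet

__all__ = [
    "PredictiveBand",
    "CheckReport",
    "posterior_predictive",
    "autocorrelation",
    "residual_stats",
    "kl_divergence",
    "check_fit",
]


@dataclass
class PredictiveBand:
    """Pointwise median and central credible band per output channel."""

    t: np.ndarray
    median: dict[str, np.ndarray]
    lower: dict[str, np.ndarray]
    upper: dict[str, np.ndarray]
    level: float
    n_draws: int


def posterior_predictive(
    posterior: Posterior,
    model: ModelDefinition,
    inputs: TimeSeriesSet,
    channels: list[str] | None = None,
    n_draws: int = 25,
    level: float = 0.95,
    seed: int | None = None,
    n_substeps: int = 2,
) -> PredictiveBand:
    """Simulate ``n_draws`` with-replacement posterior samples and aggregate.

    Returns the pointwise median and the central ``level`` credible interval
    (percentile band, 2.5/97.5 by default) on the input time grid.
    """
    if posterior.n_accepted == 0 or posterior.distances.size == 0:
        raise ValueError("posterior is empty; nothing to sample")
    channels = channels or model.output_names
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, posterior.distances.size, size=n_draws)
    thetas = {k: v[idx] for k, v in posterior.draws.items()}
    sims = simulate_batch(model, thetas, inputs, n_substeps)
    alpha = (1.0 - level) / 2.0
    med, lo, hi = {}, {}, {}
    for ch in channels:
        Y = sims[ch]
        med[ch] = np.median(Y, axis=0)
        lo[ch] = np.quantile(Y, alpha, axis=0)
        hi[ch] = np.quantile(Y, 1.0 - alpha, axis=0)
    return PredictiveBand(inputs.t.copy(), med, lo, hi, level, n_draws)


def autocorrelation(y, max_lag: int) -> np.ndarray:
    """Normalised autocorrelation r(0..max_lag); r(0) = 1 by construction."""
    y = np.asarray(y, dtype=float)
    if y.size <= max_lag:
        raise ValueError(f"series length {y.size} must exceed max_lag {max_lag}")
    yc = y - y.mean()
    denom = float(np.dot(yc, yc))
    if denom == 0:
        raise ValueError("zero-variance series has undefined autocorrelation")
    return np.array([np.dot(yc[: y.size - lag], yc[lag:]) / denom for lag in range(max_lag + 1)])


def residual_stats(observed, predicted_median, bins: int = 30):
    """Residual summary for one channel; residual = observed − predicted.

    Returns a dict with mean, sd, histogram (counts, edges) and Q-Q point
    pairs: standard-normal theoretical quantiles vs ordered standardised
    residuals.
    """
    observed = np.asarray(observed, dtype=float)
    predicted_median = np.asarray(predicted_median, dtype=float)
    if observed.shape != predicted_median.shape:
        raise ValueError("observed and predicted series must have equal length")
    res = observed - predicted_median
    mean = float(res.mean())
    sd = float(res.std(ddof=1)) if res.size > 1 else 0.0
    counts, edges = np.histogram(res, bins=bins)
    if sd > 0:
        std_res = np.sort((res - mean) / sd)
        n = res.size
        theor = sstats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    else:
        std_res = np.zeros_like(res)
        theor = np.zeros_like(res)
    return {
        "mean": mean,
        "sd": sd,
        "hist_counts": counts,
        "hist_edges": edges,
        "qq_theoretical": theor,
        "qq_sample": std_res,
    }


def kl_divergence(prior_samples, posterior_samples, bins: int = 50,
                  support: tuple[float, float] | None = None) -> float:
    """KL(posterior ‖ prior) in nats from shared-bin histograms.

    Bins span the prior support (by default the sample range of the prior,
    which for uniform priors is the support up to edge effects). Posterior
    mass falling in a zero-prior bin would make the divergence infinite and
    raises instead — it cannot occur when the posterior was drawn inside a
    uniform prior's support. Zero posterior bins contribute zero.
    """
    p = np.asarray(prior_samples, dtype=float)
    q = np.asarray(posterior_samples, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if support is None:
        support = (float(p.min()), float(p.max()))
    edges = np.linspace(support[0], support[1], bins + 1)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(np.clip(q, support[0], support[1]), bins=edges)
    fp = hp / hp.sum()
    fq = hq / hq.sum()
    bad = (fq > 0) & (fp == 0)
    if bad.any():
        raise ValueError("posterior mass in a zero-prior bin; KL undefined")
    m = fq > 0
    return float(np.sum(fq[m] * np.log(fq[m] / fp[m])))


@dataclass
class CheckReport:
    """Per-channel predictive checks and per-parameter information gain."""

    channels: dict[str, dict]
    kl: dict[str, float]
    level: float
    n_draws: int

    def to_dict(self) -> dict:
        out = {"level": self.level, "n_draws": self.n_draws, "channels": {}, "kl_nats": self.kl}
        for ch, d in self.channels.items():
            out["channels"][ch] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()
            }
        return out


def check_fit(
    posterior: Posterior,
    model: ModelDefinition,
    observed: TimeSeriesSet,
    priors: PriorSet,
    channels: list[str],
    n_draws: int = 25,
    max_lag: int = 60,
    seed: int | None = None,
    n_prior_samples: int = 10000,
) -> tuple[CheckReport, PredictiveBand]:
    """Run the full model-checking suite for a fitted posterior.

    For each fitted channel: observed and predictive autocorrelation, residual
    statistics against the predictive median, Q-Q points. For each fitted
    parameter: KL(posterior ‖ prior) in nats estimated on the prior support.
    """
    from .rejection import sample_prior
    from .timeseries import normalise_delta

    band = posterior_predictive(posterior, model, observed, channels, n_draws, seed=seed)
    report_channels = {}
    for ch in channels:
        y = observed[ch]
        y = normalise_delta(y) if ch in model.delta_outputs else np.asarray(y, float)
        pred = band.median[ch]
        lag = min(max_lag, y.size - 1)
        entry = residual_stats(y, pred)
        entry["acf_observed"] = autocorrelation(y, lag)
        entry["acf_predicted"] = autocorrelation(pred, lag)
        report_channels[ch] = entry
    rng = np.random.default_rng(seed)
    prior_draws = sample_prior(priors, n_prior_samples, rng)
    kl = {
        name: kl_divergence(prior_draws[name], posterior.draws[name],
                            support=priors.bounds[name])
        for name in priors.names
    }
    return CheckReport(report_channels, kl, band.level, n_draws), band
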