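"""Summary statistics and distances for comparing simulated and observed signals.

The scaled baseline-to-peak (SBTP) statistic summarises a time series by its
largest excursion from the first sample, scaled by the range of a reference
("default") signal so that outputs spanning very different magnitudes (TOI in
percent vs ΔCCO in tenths of a μM) contribute comparably. Pointwise distances
(Euclidean, RMSE, NRMSE) are provided for fitting; NRMSE divides the RMSE by
the range of the *observed* series, again to put channels on a common scale.
"""

from __future__ import annotations

import numpy as np

from .timeseries import TimeSeriesSet

__all__ = [
    "baseline_to_peak",
    "sbtp",
    "sbtp_distance",
    "euclidean",
    "rmse",
    "nrmse",
    "combined_distance",
    "DISTANCE_KINDS",
]


def _as1d(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("series must be non-empty")
    return np.atleast_1d(y)


def baseline_to_peak(y) -> float:
    """Largest absolute excursion from the baseline (first sample).

    Returns ``max(|max(y) - y[0]|, |min(y) - y[0]|)``.
    """
    y = _as1d(y)
    y0 = y[0]
    return float(max(abs(y.max() - y0), abs(y.min() - y0)))


def sbtp(y, reference_range: float) -> float:
    """Scaled baseline-to-peak: ``baseline_to_peak(y) / reference_range``.

    ``reference_range`` is the range max−min of the default/reference signal
    and must be strictly positive (a flat reference makes the scale undefined).
    """
    if reference_range <= 0:
        raise ValueError(f"reference_range must be > 0, got {reference_range}")
    return baseline_to_peak(y) / reference_range


def sbtp_distance(y_default, y_i) -> float:
    """Distance between the SBTP summaries of a reference and a candidate series.

    Both series are scaled by the range of ``y_default``; the distance is the
    absolute difference of the two SBTP values (the Euclidean distance of a
    single scalar pair).
    """
    y_default = _as1d(y_default)
    ref_range = float(y_default.max() - y_default.min())
    if ref_range <= 0:
        raise ValueError("flat reference series: SBTP scale undefined")
    return abs(sbtp(y_default, ref_range) - sbtp(y_i, ref_range))


def _check_lengths(x1, x2):
    x1, x2 = _as1d(x1), _as1d(x2)
    if x1.size != x2.size:
        raise ValueError(f"length mismatch: {x1.size} vs {x2.size}")
    return x1, x2


def euclidean(x1, x2) -> float:
    """L2 distance sqrt(sum((x1-x2)^2)) between equal-length series."""
    x1, x2 = _check_lengths(x1, x2)
    return float(np.sqrt(np.sum((x1 - x2) ** 2)))


def rmse(x1, x2) -> float:
    """Root-mean-square error between equal-length series."""
    x1, x2 = _check_lengths(x1, x2)
    return float(np.sqrt(np.mean((x1 - x2) ** 2)))


def nrmse(x1, x2) -> float:
    """RMSE normalised by the range of ``x1`` (the observed/reference series).

    Argument order matters: normalisation uses ``x1.max() - x1.min()``.
    Invariant under a common positive affine rescaling of both series.
    """
    x1, x2 = _check_lengths(x1, x2)
    rng = float(x1.max() - x1.min())
    if rng <= 0:
        raise ValueError("reference series x1 has zero range; NRMSE undefined")
    return rmse(x1, x2) / rng


DISTANCE_KINDS = {
    "euclidean": euclidean,
    "rmse": rmse,
    "nrmse": nrmse,
    "sbtp": sbtp_distance,
}


def combined_distance(
    observed: TimeSeriesSet,
    simulated: TimeSeriesSet,
    channels: list[str],
    kind: str = "nrmse",
    weights: dict[str, float] | None = None,
) -> tuple[float, dict[str, float]]:
    """Multi-output distance: weighted sum of per-channel distances.

    Default weights are 1 for every channel (equal weighting is the point of
    the NRMSE normalisation). Returns ``(total, per_channel)``. For ``kind=
    'sbtp'`` the observed channel is the reference series.
    """
    if kind not in DISTANCE_KINDS:
        raise ValueError(f"unknown distance kind {kind!r}; choose from {sorted(DISTANCE_KINDS)}")
    fn = DISTANCE_KINDS[kind]
    per_channel: dict[str, float] = {}
    total = 0.0
    for ch in channels:
        if ch not in observed:
            raise KeyError(f"channel {ch!r} missing from observed data")
        if ch not in simulated:
            raise KeyError(f"channel {ch!r} missing from simulation")
        d = fn(observed[ch], simulated[ch])
        per_channel[ch] = d
        total += (weights.get(ch, 1.0) if weights else 1.0) * d
    return total, per_channel
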