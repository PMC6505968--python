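"""Uniformly sampled, named multi-channel time series.

All signals in this package — systemic inputs (ABP, SaO2, PaCO2) and NIRS
outputs (TOI, ΔHbO2, ΔHHb, ΔHbT, ΔHbD, ΔCCO) — live on a shared, strictly
increasing, uniform time grid (seconds; 1 Hz after preprocessing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesSet", "normalise_delta", "read_timeseries_csv", "write_timeseries_csv"]


@dataclass
class TimeSeriesSet:
    """Named channels sharing one uniform time grid.

    Parameters
    ----------
    t : array of float
        Time in seconds, strictly increasing and uniformly spaced.
    channels : dict of str -> array
        Each value has the same length as ``t``.
    units : dict of str -> str, optional
        Unit string per channel (informational).
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValueError("time grid must be a non-empty 1-D array")
        dt = np.diff(self.t)
        if self.t.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-10):
                raise ValueError(
                    "time grid must be uniform; resample first (see preprocess.resample_to_1hz)"
                )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, vals in self.channels.items():
            if vals.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length {vals.size} != grid length {self.t.size}")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def with_channels(self, extra: dict[str, np.ndarray], units: dict[str, str] | None = None) -> "TimeSeriesSet":
        ch = dict(self.channels)
        ch.update(extra)
        u = dict(self.units)
        if units:
            u.update(units)
        return TimeSeriesSet(self.t.copy(), ch, u)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, **self.channels})

    def interpolator(self, names: list[str]):
        """Return f(t) -> array of channel values, linear between samples.

        Physiological inputs at 1 Hz are smooth; linear interpolation is used
        whenever an integrator requests values between grid points.
        """
        t = self.t
        cols = [self.channels[n] for n in names]

        def f(tq):
            return np.array([np.interp(tq, t, c) for c in cols])

        return f


def normalise_delta(y: np.ndarray) -> np.ndarray:
    """Shift a series so it starts at exactly zero (value minus first sample).

    NIRS concentration changes are measured relative to the record start, so
    both data and model Δ-outputs are normalised to an initial value of 0.
    Idempotent; raises on an empty series.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot normalise an empty series")
    return y - y[0]


def write_timeseries_csv(ts: TimeSeriesSet, path) -> None:
    """Write a TimeSeriesSet to CSV with a leading ``t`` column.

    Values are written with 17 significant digits so a write→read round trip
    is exact to double precision.
    """
    ts.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_timeseries_csv(path) -> TimeSeriesSet:
    """Read a CSV with a ``t`` column (seconds) plus named channels."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise ValueError(f"{path}: CSV must contain a 't' column in seconds")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: 't' column must be strictly increasing")
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "t"}
    return TimeSeriesSet(t, channels)
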