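"""Signal preprocessing: low-pass filtering and resampling to the 1 Hz grid."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["butterworth_lowpass", "resample_to_1hz"]


def butterworth_lowpass(
    y,
    fs_hz: float,
    order: int = 5,
    cutoff_hz: float = 0.05,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter (default 5th order, 0.05 Hz cut-off).

    By default the filter is applied forward-backward (``filtfilt``) for zero
    phase lag, which squares the magnitude response; set ``zero_phase=False``
    for a single causal pass. DC gain is 1 either way.
    """
    y = np.asarray(y, dtype=float)
    if cutoff_hz >= fs_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {fs_hz / 2} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, y)
    return sps.sosfilt(sos, y)


def resample_to_1hz(y, fs_in: float) -> np.ndarray:
    """Resample to 1 Hz by averaging within whole-second bins.

    Bin-mean resampling is inherently anti-aliased for the smooth
    physiological signals handled here. ``fs_in`` must be >= 1 Hz and an
    integer number of samples per second; 1 Hz input is returned unchanged.
    """
    y = np.asarray(y, dtype=float)
    if fs_in < 1:
        raise ValueError("input rate must be at least 1 Hz")
    k = fs_in
    if abs(k - round(k)) > 1e-9:
        raise ValueError("only integer samples-per-second rates are supported")
    k = int(round(k))
    if k == 1:
        return y.copy()
    n_out = y.size // k
    return y[: n_out * k].reshape(n_out, k).mean(axis=1)
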