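"""Shared band-pass / resampling primitives for the event detectors.

Both detectors work on traces downsampled to 100 Hz and band-pass filtered
with a 4th-order Butterworth applied forward-and-backward (zero phase, so
event times are not shifted by group delay).  Decimation goes through
``scipy.signal.resample_poly``, whose polyphase FIR provides the
anti-alias low-pass.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = ["downsample", "bandpass", "moving_rms"]


def downsample(x: np.ndarray, sfreq: float, target: float) -> np.ndarray:
    """Resample ``x`` from ``sfreq`` to ``target`` Hz (anti-aliased)."""
    if target > sfreq:
        raise ValueError("upsampling not supported")
    if abs(sfreq - target) < 1e-9:
        return np.asarray(x, dtype=float)
    frac = Fraction(target / sfreq).limit_denominator(1000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if fs < 2.0 * high:
        raise ValueError(
            f"sampling rate {fs} Hz below Nyquist requirement for band edge {high} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def moving_rms(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Sliding-window RMS envelope (centered, 1-sample step)."""
    from scipy.ndimage import uniform_filter1d

    n = max(1, int(round(window_s * fs)))
    power = uniform_filter1d(np.asarray(x, dtype=float) ** 2, size=n, mode="nearest")
    return np.sqrt(power)
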