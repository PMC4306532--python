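"""Zero-phase Butterworth filtering helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["design_bandpass", "bandpass", "crop_window"]


def design_bandpass(band, sfreq: float, order: int = 4):
    """Second-order sections for a Butterworth band-pass (or low-pass).

    ``band = (low, high)``; ``low`` of 0/None yields a low-pass at ``high``.
    """
    low, high = band
    nyq = sfreq / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz >= Nyquist ({nyq} Hz)")
    if low is None or low <= 0:
        return signal.butter(order, high, btype="lowpass", fs=sfreq, output="sos")
    return signal.butter(order, [low, high], btype="bandpass", fs=sfreq, output="sos")


def bandpass(x: np.ndarray, band, sfreq: float, order: int = 4, axis: int = -1):
    """Forward-backward (zero-phase) Butterworth filter with mirror padding."""
    sos = design_bandpass(band, sfreq, order)
    return signal.sosfiltfilt(sos, x, axis=axis, padtype="even")


def crop_window(n_samples: int, t0: float, sfreq: float, window):
    """Sample-index slice of ``window = (start, stop)`` seconds (t rel. onset)."""
    start = int(round((window[0] - t0) * sfreq))
    stop = int(round((window[1] - t0) * sfreq))
    start = max(start, 0)
    stop = min(stop, n_samples)
    if stop <= start:
        raise ValueError(f"window {window} falls outside the epoch")
    return slice(start, stop)
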