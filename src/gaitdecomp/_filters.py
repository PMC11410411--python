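"""Zero-phase low-pass filtering helpers used by events, metrics and decomposition."""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["lowpass"]


def lowpass(x: np.ndarray, sample_rate: float, cutoff: float | None, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis.

    Returns ``x`` unchanged when ``cutoff`` is None, non-positive, or at/above
    the Nyquist frequency, or when the series is too short for stable
    forward-backward filtering.
    """
    x = np.asarray(x, dtype=float)
    if cutoff is None or cutoff <= 0:
        return x
    nyq = sample_rate / 2.0
    if cutoff >= nyq:
        return x
    sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
    # filtfilt needs padlen < n; fall back to the raw series for very short input
    padlen = 3 * (2 * order + 1)
    if x.shape[0] <= padlen:
        return x
    return signal.sosfiltfilt(sos, x, axis=0)
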