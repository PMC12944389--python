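"""Front-end filtering for raw sEMG: band-pass 10-500 Hz plus 50 Hz notch.

Surface EMG carries physiological power roughly between 10 and 500 Hz;
below that sit baseline drift and motion artifacts, and mains pickup adds
a narrow 50 Hz line.  Both filters are applied zero-phase
(forward-backward), so burst onsets are not delayed -- interval
thresholding downstream depends on zero-crossing timing.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signal_model import Signal

__all__ = ["bandpass", "notch", "preprocess"]


def _filtfilt(sos_or_ba, samples: np.ndarray, *, is_sos: bool) -> np.ndarray:
    # Reflective padding of one settling length suppresses startup
    # transients on short records; scipy's default padlen is tiny.
    n = samples.size
    if is_sos:
        padlen = min(n - 1, 3 * 2 * sos_or_ba.shape[0] * 10)
        return sps.sosfiltfilt(sos_or_ba, samples, padlen=padlen)
    b, a = sos_or_ba
    padlen = min(n - 1, 3 * max(len(b), len(a)) * 10)
    return sps.filtfilt(b, a, samples, padlen=padlen)


def bandpass(
    signal: Signal, low: float = 10.0, high: float = 500.0, order: int = 4
) -> Signal:
    """Zero-phase Butterworth band-pass.

    ``order`` is the one-way filter order (default 4); forward-backward
    application doubles the effective roll-off and cancels phase.

    Raises
    ------
    ValueError
        Unless ``0 < low < high < fs/2``.
    """
    nyq = signal.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band [{low}, {high}] Hz invalid for fs={signal.fs} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=signal.fs, output="sos")
    return signal.with_samples(_filtfilt(sos, signal.samples, is_sos=True))


def notch(signal: Signal, freq: float = 50.0, q: float = 30.0) -> Signal:
    """Zero-phase IIR notch suppressing power-line interference at ``freq``.

    Quality factor ``q`` (default 30) keeps the stop band narrow so
    neighbouring EMG content is barely touched.
    """
    nyq = signal.fs / 2.0
    if not (0 < freq < nyq):
        raise ValueError(f"notch frequency {freq} Hz invalid for fs={signal.fs} Hz")
    b, a = sps.iirnotch(freq, q, fs=signal.fs)
    return signal.with_samples(_filtfilt((b, a), signal.samples, is_sos=False))


def preprocess(
    signal: Signal,
    bp_low: float = 10.0,
    bp_high: float = 500.0,
    bp_order: int = 4,
    notch_freq: float = 50.0,
    notch_q: float = 30.0,
) -> Signal:
    """Standard sEMG front end: band-pass then mains notch.

    Length, sampling rate and rest span are preserved.
    """
    return notch(
        bandpass(signal, bp_low, bp_high, bp_order), notch_freq, notch_q
    )
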