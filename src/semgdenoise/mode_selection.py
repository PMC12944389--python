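"""Physiological-band mode screening via mean instantaneous frequency.

After decomposition, modes whose mean instantaneous frequency (MIF) falls
outside the physiologically meaningful sEMG band are discarded before
thresholding and reconstruction: very low-MIF modes carry baseline
drift/motion artifact remnants, very high-MIF modes carry out-of-band
noise.  The MIF is the average derivative of the unwrapped analytic
phase; the first and last 5% of samples are trimmed from the average to
avoid Hilbert edge artifacts.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert

from .vmd import ModeSet

__all__ = ["mean_instfreq", "select_modes"]


def mean_instfreq(mode: np.ndarray, fs: float, edge_trim: float = 0.05) -> float:
    """Mean instantaneous frequency of a mode, in Hz.

    Computed as the mean of ``d(phase)/dt / (2*pi)`` over interior
    samples (``edge_trim`` fraction excluded at each end), clipped to
    ``[0, fs/2]``.  An all-zero mode has no phase; it is reported as
    0 Hz with a warning.
    """
    mode = np.asarray(mode, dtype=float)
    if mode.size < 16:
        raise ValueError("mode too short for instantaneous frequency")
    if not np.any(mode):
        warnings.warn("all-zero mode; mean instantaneous frequency set to 0 Hz",
                      stacklevel=2)
        return 0.0
    phase = np.unwrap(np.angle(hilbert(mode)))
    inst_freq = np.diff(phase) * fs / (2.0 * np.pi)
    trim = int(edge_trim * inst_freq.size)
    interior = inst_freq[trim : inst_freq.size - trim] if trim > 0 else inst_freq
    return float(np.clip(np.mean(interior), 0.0, fs / 2.0))


def select_modes(
    modeset: ModeSet,
    band: tuple[float, float] = (10.0, 500.0),
) -> list[int]:
    """Indices of modes whose MIF lies inside ``band`` (inclusive).

    Order is preserved.  If no mode passes, all indices are returned
    (with a warning): silently deleting the whole signal would be worse
    than skipping the screen.
    """
    low, high = band
    kept = [
        k
        for k in range(modeset.K)
        if low <= mean_instfreq(modeset.modes[k], modeset.fs) <= high
    ]
    if not kept:
        warnings.warn(
            "no mode inside the physiological band; retaining all modes",
            stacklevel=2,
        )
        return list(range(modeset.K))
    return kept
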