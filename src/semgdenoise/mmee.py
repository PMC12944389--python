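"""Minimum mode envelope entropy (MMEE): the VMD parameter-search fitness.

Burst-structured muscle activity concentrates its Hilbert envelope in
time, giving a low Shannon entropy of the time-normalised envelope,
whereas a noise-dominated mode has a near-uniform envelope and entropy
close to the ``log2(N)`` maximum.  A well-parameterised decomposition
therefore produces at least one low-entropy mode, and the fitness is the
minimum envelope entropy across modes.  Near-empty modes would win that
minimum trivially (a short transient in an otherwise dead mode has very
low entropy), so the minimisation only considers modes carrying at least
``energy_gate`` of the total mode energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .vmd import ModeSet

__all__ = [
    "envelope",
    "shannon_entropy_bits",
    "envelope_entropy",
    "mmee_fitness",
    "EnvelopeEntropyReport",
]


@dataclass(frozen=True)
class EnvelopeEntropyReport:
    """Per-mode envelope entropies (bits), energy fractions, and the
    energy-gated minimum used as the optimisation fitness."""

    entropies: np.ndarray
    energy_fractions: np.ndarray
    gated_min: float


def envelope(mode: np.ndarray) -> np.ndarray:
    """Hilbert envelope ``a(t) = |mode + j*H(mode)|`` of a mode.

    Non-negative, same length as the input.  An all-zero mode yields an
    all-zero envelope (handled by the entropy fallback downstream).
    """
    mode = np.asarray(mode, dtype=float)
    if mode.size < 4:
        raise ValueError("mode too short for an envelope")
    if not np.all(np.isfinite(mode)):
        raise ValueError("mode must be finite")
    return np.abs(hilbert(mode))


def shannon_entropy_bits(envelope_series: np.ndarray) -> float:
    """Shannon entropy (bits) of a non-negative series normalised to a
    probability sequence ``p_j = a_j / sum(a)``; bounded by ``[0, log2 N]``.

    A zero-mass series carries no information about temporal structure
    and is assigned the maximal ``log2 N`` (with a warning) so dead modes
    can never win the MMEE minimum.
    """
    a = np.asarray(envelope_series, dtype=float)
    if np.any(a < 0):
        raise ValueError("envelope must be non-negative")
    total = a.sum()
    if total <= 0:
        warnings.warn("zero-mass envelope; entropy set to log2(N)", stacklevel=2)
        return float(np.log2(a.size))
    p = a / total
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def envelope_entropy(mode: np.ndarray) -> float:
    """Shannon entropy (bits) of the time-normalised Hilbert envelope of
    ``mode`` (see :func:`shannon_entropy_bits`)."""
    return shannon_entropy_bits(envelope(mode))


def mmee_report(modeset: ModeSet, energy_gate: float = 0.01) -> EnvelopeEntropyReport:
    """Full per-mode report behind :func:`mmee_fitness`."""
    if modeset.K < 1:
        raise ValueError("empty ModeSet")
    energies = np.array([float(np.dot(m, m)) for m in modeset.modes])
    total = energies.sum()
    fractions = energies / total if total > 0 else np.full(modeset.K, 1.0 / modeset.K)
    entropies = np.array([envelope_entropy(m) for m in modeset.modes])
    passed = fractions >= energy_gate
    if not np.any(passed):
        passed = np.ones(modeset.K, dtype=bool)  # fallback: gate everything in
    gated_min = float(entropies[passed].min())
    return EnvelopeEntropyReport(entropies, fractions, gated_min)


def mmee_fitness(modeset: ModeSet, energy_gate: float = 0.01) -> float:
    """Minimum envelope entropy over modes whose energy fraction is at
    least ``energy_gate`` (default 1%); falls back to all modes if none
    pass the gate."""
    return mmee_report(modeset, energy_gate).gated_min
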