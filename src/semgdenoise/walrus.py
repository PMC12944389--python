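"""Walrus Optimizer (WO): a population metaheuristic on a box domain.

The algorithm mimics a walrus herd's response to environmental cues.  A
*danger signal* ``A * R`` (with ``A = 2*gamma``, ``gamma`` decaying
linearly from 1 to 0, and ``R`` uniform on [-1, 1]) gates the population
between two regimes each iteration:

* ``|danger| >= 1`` — **migration**: every individual steps by
  ``(X_m - X_n) * beta * r^2`` toward the span between two random herd
  members, with a sigmoidal step-control factor ``beta`` that shrinks as
  iterations progress — global exploration.
* ``|danger| < 1`` — **reproduction**: role-based updates.  Females blend
  attraction to a paired male and to the global best, weighted ``gamma``
  vs ``1 - gamma``.  Males scout: a bounded random walk mixing attraction
  to the best and to a random partner, with step scaled by ``gamma``.
  Juveniles normally drift toward the best with a Levy-flight
  perturbation; when the *safety signal* (uniform on (0, 1)) drops below
  0.5 they flee toward a safety position ``O = X_best + juvenile * LF``
  via ``X_new = (O - X) * P`` with distress coefficient ``P ~ U(0, 1)``.

Levy steps use Mantegna's method with stability exponent 1.5.  Positions
are clamped to the box after every update, the whole population is
re-evaluated each iteration, and the best-so-far is tracked elitistically,
so the fitness history is non-increasing.  Dimensions flagged as integer
are kept continuous internally and rounded only at objective evaluation
(and in the reported optimum), preserving search smoothness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["WOConfig", "OptResult", "wo_minimize"]


@dataclass(frozen=True)
class WOConfig:
    """Population and search-space controls for :func:`wo_minimize`."""

    bounds: Sequence[tuple[float, float]]
    pop_size: int = 20
    max_iter: int = 50
    integer_dims: Sequence[bool] | None = None
    role_fractions: tuple[float, float, float] = (0.45, 0.45, 0.10)
    levy_exponent: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        for lo, hi in self.bounds:
            if not lo <= hi:
                raise ValueError(f"invalid bound [{lo}, {hi}]")
        if abs(sum(self.role_fractions) - 1.0) > 1e-9:
            raise ValueError("role_fractions must sum to 1")
        if self.integer_dims is not None and len(self.integer_dims) != len(self.bounds):
            raise ValueError("integer_dims mask must match bounds dimension")


@dataclass(frozen=True)
class OptResult:
    """Best position/fitness plus the per-iteration best-so-far trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int


def _levy_step(rng: np.random.Generator, shape, exponent: float) -> np.ndarray:
    # Mantegna's algorithm for symmetric alpha-stable steps.
    beta = exponent
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma_u = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1 / beta)


def wo_minimize(
    objective: Callable[[np.ndarray], float], config: WOConfig
) -> OptResult:
    """Minimise ``objective`` over the box given in ``config``.

    The objective receives positions already clamped to the box (with
    integer dimensions rounded); non-finite returns are treated as +inf
    so the individual survives but can never become the incumbent.

    Returns
    -------
    OptResult
        ``history`` has length ``max_iter`` and is non-increasing;
        ``best_fitness`` equals its last entry.  Identical config + seed
        reproduce the result exactly.
    """
    rng = np.random.default_rng(config.seed)
    lower = np.array([b[0] for b in config.bounds], dtype=float)
    upper = np.array([b[1] for b in config.bounds], dtype=float)
    dim = lower.size
    int_mask = (
        np.asarray(config.integer_dims, dtype=bool)
        if config.integer_dims is not None
        else np.zeros(dim, dtype=bool)
    )
    N, I = config.pop_size, config.max_iter

    def snap(pos: np.ndarray) -> np.ndarray:
        out = pos.copy()
        out[int_mask] = np.round(out[int_mask])
        return out

    def evaluate(pos: np.ndarray) -> float:
        val = float(objective(snap(pos)))
        return val if math.isfinite(val) else math.inf

    X = rng.uniform(lower, upper, size=(N, dim))
    fitness = np.array([evaluate(x) for x in X])
    evaluations = N
    if not np.any(np.isfinite(fitness)):
        raise ValueError("objective non-finite over the whole initial population")

    best_idx = int(np.argmin(fitness))
    best_pos = X[best_idx].copy()
    best_fit = float(fitness[best_idx])

    n_male = max(1, int(round(config.role_fractions[0] * N)))
    n_female = max(1, int(round(config.role_fractions[1] * N)))
    n_male = min(n_male, N - 2)
    n_female = min(n_female, N - n_male - 1)
    # Remaining individuals are juveniles (at least one).

    history = np.empty(I)
    for l in range(1, I + 1):
        gamma = 1.0 - l / I
        A = 2.0 * gamma
        R = 2.0 * rng.random() - 1.0
        danger = A * R
        safety = rng.random()

        if abs(danger) >= 1.0:
            # Migration: step along the span between two random members.
            beta = 1.0 - 1.0 / (1.0 + math.exp(-10.0 * (l - 0.5 * I) / I))
            for i in range(N):
                m, n = rng.integers(0, N, size=2)
                r3 = rng.random()
                X[i] = X[i] + (X[m] - X[n]) * beta * r3**2
        else:
            males = slice(0, n_male)
            females = slice(n_male, n_male + n_female)
            juveniles = slice(n_male + n_female, N)

            # Males scout: bounded random walk toward best and a partner.
            for i in range(*males.indices(N)):
                partner = int(rng.integers(0, N))
                r_a, r_b = rng.random(dim), rng.random(dim)
                X[i] = X[i] + gamma * r_a * (best_pos - X[i]) + (1.0 - gamma) * r_b * (
                    X[partner] - X[i]
                )

            # Females: blend attraction to a paired male and the best.
            for j, i in enumerate(range(*females.indices(N))):
                mate = j % n_male
                X[i] = (
                    X[i]
                    + gamma * (X[mate] - X[i])
                    + (1.0 - gamma) * (best_pos - X[i])
                )

            # Juveniles: flee toward the safety position under distress,
            # otherwise drift toward the best with a Levy perturbation.
            for i in range(*juveniles.indices(N)):
                if safety < 0.5:
                    LF = _levy_step(rng, dim, config.levy_exponent)
                    O = best_pos + X[i] * LF
                    P = rng.random()
                    X[i] = (O - X[i]) * P
                else:
                    r = rng.random(dim)
                    LF = _levy_step(rng, dim, config.levy_exponent)
                    X[i] = X[i] + r * (best_pos - X[i]) + 0.05 * LF * (upper - lower)

        np.clip(X, lower, upper, out=X)
        fitness = np.array([evaluate(x) for x in X])
        evaluations += N
        idx = int(np.argmin(fitness))
        if fitness[idx] < best_fit:
            best_fit = float(fitness[idx])
            best_pos = X[idx].copy()
        history[l - 1] = best_fit

    return OptResult(
        best_position=snap(best_pos),
        best_fitness=best_fit,
        history=history,
        evaluations=evaluations,
    )
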