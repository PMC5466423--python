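"""Closed-form survival of rare beneficial mutants under periodic bottlenecks.

A symbiont population grows by binary fission for ``tau`` generations between
successive host-imposed bottlenecks (recruitment into a new host, or the daily
venting of the light organ). A beneficial mutant lineage founded by a single
cell during generation ``t`` of the growth phase risks stochastic loss at every
bottleneck. To first order in the selective advantage ``s`` (Wahl-Gerrish
approximation for periodically bottlenecked populations), the probability that
the lineage ultimately escapes extinction is

    pi(t, s) = s * tau * ln(2) / 2**(t - 1)

and the extinction probability is ``V = 1 - pi``. The raw expression can exceed
one for strongly beneficial, early-arising mutants; probabilities are clamped
to [0, 1] unless the raw value is requested.

Conventions
-----------
``t = 1`` means the mutant arises during the first generation of the growth
phase, so ``tau`` generations elapse before the next bottleneck. ``s`` is on
the simulator (doubling-exponent) scale: a mutant multiplies by ``2**(1 + s)``
per generation while the ancestor doubles.

The approximation is accurate only for small ``s * tau``; the stochastic
simulator (:mod:`bottlepass.simulate`) provides the numerical check and the
methods note documents where the formula breaks down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "BottleneckRegime",
    "SurvivalQuery",
    "SurvivalSurface",
    "RECRUITMENT",
    "VENTING",
    "survival_probability",
    "extinction_probability",
    "required_selection_coefficient",
    "survival_surface",
]


@dataclass(frozen=True)
class BottleneckRegime:
    """Growth/bottleneck regime: ``tau`` generations of growth per bottleneck."""

    tau: int
    label: str = ""

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 1:
            raise DomainError(f"tau must be a positive integer, got {self.tau!r}")
        object.__setattr__(self, "tau", int(self.tau))


#: Host colonization bottleneck after inoculum growth (25 generations of growth).
RECRUITMENT = BottleneckRegime(25, "recruitment")
#: Daily venting bottleneck within the light organ (4 generations of regrowth).
VENTING = BottleneckRegime(4, "venting")


def _tau_of(regime: BottleneckRegime | int) -> int:
    if isinstance(regime, BottleneckRegime):
        return regime.tau
    tau = int(regime)
    if tau != regime or tau < 1:
        raise DomainError(f"tau must be a positive integer, got {regime!r}")
    return tau


def _validate_t_s(t: int, s: float, tau: int) -> int:
    if int(t) != t:
        raise DomainError(f"t must be an integer generation, got {t!r}")
    t = int(t)
    if not 1 <= t <= tau:
        raise DomainError(f"t must satisfy 1 <= t <= tau={tau}, got {t}")
    if s < 0 or not math.isfinite(s):
        raise DomainError(f"selection coefficient must be finite and >= 0, got {s!r}")
    return t


@dataclass(frozen=True)
class SurvivalQuery:
    """One (t, s, regime) triple for the survival approximation."""

    t: int
    s: float
    regime: BottleneckRegime

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _validate_t_s(self.t, self.s, self.regime.tau))

    def probability(self, clamp: bool = True) -> float:
        return survival_probability(self.t, self.s, self.regime, clamp=clamp)


def survival_probability(
    t: int, s: float, regime: BottleneckRegime | int, *, clamp: bool = True
) -> float:
    """Survival probability pi(t, s) of a mutant arising at generation ``t``.

    Parameters
    ----------
    t : generation of origin within the growth phase (1 <= t <= tau).
    s : selection coefficient (simulator scale, >= 0).
    regime : BottleneckRegime or integer tau.
    clamp : clamp the result to [0, 1] (default). With ``clamp=False`` the raw
        first-order value is returned for diagnostics; it may exceed one.
    """
    tau = _tau_of(regime)
    t = _validate_t_s(t, s, tau)
    raw = s * tau * LN2 / 2.0 ** (t - 1)
    if not clamp:
        return raw
    return min(max(raw, 0.0), 1.0)


def extinction_probability(
    t: int, s: float, regime: BottleneckRegime | int
) -> float:
    """Extinction probability V(t, s) = 1 - pi(t, s)."""
    return 1.0 - survival_probability(t, s, regime)


def required_selection_coefficient(
    t: int, pi_target: float, regime: BottleneckRegime | int
) -> float:
    """Selection coefficient giving survival probability ``pi_target`` at ``t``.

    Algebraic inverse of :func:`survival_probability` before clamping:
    ``s = pi_target * 2**(t-1) / (tau * ln 2)``.
    """
    tau = _tau_of(regime)
    if not 0.0 < pi_target <= 1.0:
        raise DomainError(f"pi_target must lie in (0, 1], got {pi_target!r}")
    t = _validate_t_s(t, 0.0, tau)
    return pi_target * 2.0 ** (t - 1) / (tau * LN2)


@dataclass
class SurvivalSurface:
    """Survival probabilities over a (t, s) grid for one bottleneck regime."""

    t_values: np.ndarray
    s_values: np.ndarray
    survival: np.ndarray
    regime: BottleneckRegime = field(default_factory=lambda: RECRUITMENT)

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=int)
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.survival.shape != (self.t_values.size, self.s_values.size):
            raise UsageError("survival matrix shape inconsistent with axis lists")
        if np.any(self.survival < 0.0) or np.any(self.survival > 1.0):
            raise DomainError("survival probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Grid as a DataFrame: rows indexed by t, columns by s."""
        return pd.DataFrame(
            self.survival,
            index=pd.Index(self.t_values, name="t"),
            columns=pd.Index(self.s_values, name="s"),
        )


def survival_surface(
    t_values, s_values, regime: BottleneckRegime | int, *, clamp: bool = True
) -> SurvivalSurface:
    """Evaluate the survival approximation over a grid of (t, s) values."""
    tau = _tau_of(regime)
    t_arr = np.atleast_1d(np.asarray(t_values))
    s_arr = np.atleast_1d(np.asarray(s_values, dtype=float))
    if t_arr.size == 0 or s_arr.size == 0:
        raise UsageError("survival_surface requires non-empty t and s axes")
    grid = np.empty((t_arr.size, s_arr.size), dtype=float)
    for i, t in enumerate(t_arr):
        for j, s in enumerate(s_arr):
            grid[i, j] = survival_probability(int(t), float(s), tau, clamp=clamp)
    reg = regime if isinstance(regime, BottleneckRegime) else BottleneckRegime(tau)
    return SurvivalSurface(t_arr, s_arr, grid, reg)
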