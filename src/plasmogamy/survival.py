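"""Mass-dependent survival functions and environment descriptions.

Daughter cells of mass ``m`` are exposed to extrinsic mortality once per
growth cycle.  Two survival families are provided:

* the Vance family ``S(m; beta) = exp(-beta/m)``, where ``beta`` is the
  environmental harshness (larger ``beta`` = harsher environment, smaller
  cells die more).  The function is strictly increasing in mass and convex
  for ``m < beta/2``, which implicitly encodes a minimum viable cell size.
* a threshold-linear family ``S(m; gamma) = 1 - exp(-gamma*m)`` for
  ``m >= m_min`` and ``0`` below, which makes the minimum viable size
  ``m_min`` explicit.  Here larger ``gamma`` means a *more benign*
  environment (survival rises faster with mass).

Fused cells survive at the total mass of the fusing pair, which is the
source of the survival advantage that can select for binary cell fusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Environment",
    "SurvivalModel",
    "EnvironmentSchedule",
    "vance_survival",
    "threshold_survival",
    "survival",
    "fused_survival",
    "harsher_than",
]

Family = Literal["vance", "threshold_linear"]


@dataclass(frozen=True)
class Environment:
    """A single environment: a positive harshness parameter and a label.

    ``harshness`` is beta for the Vance family and gamma for the
    threshold-linear family (note the opposite orientation: large beta is
    harsh, large gamma is benign; see :func:`harsher_than`).
    """

    harshness: float
    label: str = "env"

    def __post_init__(self) -> None:
        if not self.harshness > 0:
            raise ValueError(f"harshness must be > 0, got {self.harshness}")


@dataclass(frozen=True)
class SurvivalModel:
    """A survival family plus family-specific parameters.

    ``m_min`` (minimum viable cell size) is only meaningful for the
    threshold-linear family and must stay 0 for the Vance family.
    """

    family: Family = "vance"
    m_min: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("vance", "threshold_linear"):
            raise ValueError(f"unknown survival family {self.family!r}")
        if self.m_min < 0:
            raise ValueError(f"m_min must be >= 0, got {self.m_min}")
        if self.family == "vance" and self.m_min != 0.0:
            raise ValueError("m_min only applies to the threshold_linear family")


def vance_survival(m, beta: float):
    """Vance survival probability ``exp(-beta/m)``.

    Strictly increasing in ``m``; tends to 0 as ``m -> 0+`` and to 1 as
    ``m -> inf``.  ``m == 0`` returns 0 by continuity (convenient for grid
    scans); negative masses and non-positive ``beta`` are domain errors.
    Accepts scalars or arrays in ``m``.
    """
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0):
        raise ValueError("mass m must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(m_arr > 0, np.exp(-beta / np.where(m_arr > 0, m_arr, 1.0)), 0.0)
    if np.isscalar(m) or m_arr.ndim == 0:
        return float(out)
    return out


def threshold_survival(m, gamma: float, m_min: float = 0.0):
    """Threshold-linear survival: ``1 - exp(-gamma*m)`` for ``m >= m_min``, else 0."""
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if m_min < 0:
        raise ValueError(f"m_min must be >= 0, got {m_min}")
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 0):
        raise ValueError("mass m must be >= 0")
    out = np.where(m_arr >= m_min, -np.expm1(-gamma * m_arr), 0.0)
    if np.isscalar(m) or m_arr.ndim == 0:
        return float(out)
    return out


def survival(model: SurvivalModel, m, env: Environment):
    """Survival probability of an unfused cell of mass ``m`` in ``env``."""
    if model.family == "vance":
        return vance_survival(m, env.harshness)
    return threshold_survival(m, env.harshness, model.m_min)


def fused_survival(model: SurvivalModel, m_i: float, m_j: float, env: Environment):
    """Survival of a fused cell, evaluated at the pooled mass ``m_i + m_j``.

    Because every family is non-decreasing in mass, this is never below the
    survival of either partner alone.
    """
    m_i_arr = np.asarray(m_i, dtype=float)
    m_j_arr = np.asarray(m_j, dtype=float)
    if np.any(m_i_arr <= 0) or np.any(m_j_arr <= 0):
        raise ValueError("fusing partner masses must be > 0")
    return survival(model, m_i_arr + m_j_arr, env)


def harsher_than(model: SurvivalModel, env_a: Environment, env_b: Environment) -> bool:
    """True if ``env_a`` is harsher than ``env_b`` under ``model``.

    Under the Vance family larger beta is harsher; under the
    threshold-linear family larger gamma is more benign, so the comparison
    flips.
    """
    if model.family == "vance":
        return env_a.harshness > env_b.harshness
    return env_a.harshness < env_b.harshness


@dataclass(frozen=True)
class EnvironmentSchedule:
    """How the active environment changes over growth cycles.

    Modes:

    * ``fixed`` — always the first environment.
    * ``scheduled`` — toggles between the two environments at the listed
      (strictly increasing) growth-cycle indices.
    * ``telegraph`` — two-state Markov switching with per-cycle switch
      probabilities ``lambda_12`` (env1 -> env2) and ``lambda_21``; residence
      times are geometric with means ``tau1 = 1/lambda_12`` and
      ``tau2 = 1/lambda_21``, giving long-run occupancy
      ``P1 = tau1/(tau1 + tau2)`` of environment 1.
    """

    mode: Literal["fixed", "scheduled", "telegraph"]
    environments: Sequence[Environment]
    switch_cycles: Sequence[int] = field(default_factory=tuple)
    lambda_12: float = 0.0
    lambda_21: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "scheduled", "telegraph"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        envs = tuple(self.environments)
        object.__setattr__(self, "environments", envs)
        if self.mode == "fixed":
            if len(envs) < 1:
                raise ValueError("fixed mode needs at least one environment")
        elif len(envs) != 2:
            raise ValueError(f"{self.mode} mode needs exactly two environments")
        cycles = tuple(int(c) for c in self.switch_cycles)
        object.__setattr__(self, "switch_cycles", cycles)
        if self.mode == "scheduled":
            if not cycles:
                raise ValueError("scheduled mode needs at least one switch cycle")
            if any(b <= a for a, b in zip(cycles, cycles[1:])):
                raise ValueError("switch cycles must be strictly increasing")
        if self.mode == "telegraph":
            if not (0 < self.lambda_12 <= 1 and 0 < self.lambda_21 <= 1):
                raise ValueError("telegraph rates must lie in (0, 1]")

    @property
    def tau1(self) -> float:
        return 1.0 / self.lambda_12

    @property
    def tau2(self) -> float:
        return 1.0 / self.lambda_21

    @property
    def p1(self) -> float:
        """Long-run occupancy of environment 1 in telegraph mode."""
        return self.tau1 / (self.tau1 + self.tau2)

    @staticmethod
    def fixed(env: Environment) -> "EnvironmentSchedule":
        return EnvironmentSchedule(mode="fixed", environments=(env,))

    @staticmethod
    def scheduled(env1: Environment, env2: Environment,
                  switch_cycles: Sequence[int]) -> "EnvironmentSchedule":
        return EnvironmentSchedule(mode="scheduled", environments=(env1, env2),
                                   switch_cycles=tuple(switch_cycles))

    @staticmethod
    def telegraph(env1: Environment, env2: Environment,
                  lambda_12: float, lambda_21: float) -> "EnvironmentSchedule":
        return EnvironmentSchedule(mode="telegraph", environments=(env1, env2),
                                   lambda_12=lambda_12, lambda_21=lambda_21)

    @staticmethod
    def telegraph_from_occupancy(env1: Environment, env2: Environment,
                                 p1: float, rate_scale: float) -> "EnvironmentSchedule":
        """Telegraph schedule with occupancy ``p1`` and total rate ``rate_scale``.

        ``lambda_12 = (1-p1)*rate_scale`` and ``lambda_21 = p1*rate_scale`` so
        that ``tau1/(tau1+tau2) = p1``.
        """
        if not 0 < p1 < 1:
            raise ValueError("p1 must lie in (0, 1)")
        return EnvironmentSchedule.telegraph(env1, env2,
                                             lambda_12=(1 - p1) * rate_scale,
                                             lambda_21=p1 * rate_scale)


def convexity_change_point(beta: float, lo: float | None = None, hi: float | None = None,
                           tol: float = 1e-12) -> float:
    """Mass at which the Vance survival curve switches from convex to concave.

    Located by bisecting the sign change of the second derivative; the
    analytic answer is ``beta/2``.
    """
    if lo is None:
        lo = beta / 50.0  # safely inside the convex region, no exp underflow
    if hi is None:
        hi = 2.0 * beta

    def s2(m: float) -> float:
        # analytic second derivative: beta*exp(-beta/m)*(beta - 2m)/m^4
        return beta * math.exp(-beta / m) * (beta - 2.0 * m) / m**4

    a, b = lo, hi
    if s2(a) <= 0 or s2(b) >= 0:
        raise ValueError("bracket does not straddle the convexity change")
    while b - a > tol * max(1.0, abs(b)):
        mid = 0.5 * (a + b)
        if s2(mid) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
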