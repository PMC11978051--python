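"""Switching environments with costless phenotypic plasticity.

With a plastic response, each environment's trait pair (m_i, alpha_i)
evolves under that environment's own selection gradients, time-scaled by
the occupancy P_i — the flows are decoupled and only share their initial
condition (the phenotypically undifferentiated state m_1(0)=m_2(0)=m_0,
alpha_i(0)=0).  Facultative (stress-induced) fusion is the outcome in
which fusion evolves in exactly one environment; for that the shared
initial mass must sit inside the zero-fusion basin of one environment and
outside it in the other.

Two parsimonious initial conditions are analysed: a population adapted to
environment 1 (m_0 = beta_1), and a bet-hedging population adapted to both
(m_0 = m_BH = P_1 beta_1 + (1-P_1) beta_2, the non-plastic ESS under fast
switching).  In the large-ET limit the basin test reduces to comparing m_0
with each environment's interior-saddle mass -beta_i / (2 ln(1-C)), which
yields closed-form conditions on (beta_2/beta_1, C, P_1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .adaptive_dynamics import (ADParams, ADPoint, C_LOWER, C_UPPER,
                                FlowResult, flow)

__all__ = [
    "PlasticState",
    "FacultativeVerdict",
    "plastic_flow",
    "bet_hedging_mass",
    "saddle_mass",
    "facultative_condition_adapted",
    "facultative_conditions_bethedged",
    "regime_map",
]

#: tie tolerance on basin-inequality margins; equalities count as "within
#: basin" (no fusion), the conservative classification.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class PlasticState:
    """Plastic trait state (m1, alpha1, m2, alpha2) plus occupancy P1."""

    m1: float
    alpha1: float
    m2: float
    alpha2: float
    p1: float = 0.5

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0):
            raise ValueError("masses must be > 0")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("fusion rates must be >= 0")
        if not 0.0 < self.p1 < 1.0:
            raise ValueError("P1 must lie in (0, 1)")


@dataclass(frozen=True)
class FacultativeVerdict:
    fusion_in_env1: bool
    fusion_in_env2: bool
    label: Literal["both", "neither", "facultative_env1", "facultative_env2"]
    conditions: dict

    def __post_init__(self) -> None:
        expected = {
            (True, True): "both",
            (False, False): "neither",
            (True, False): "facultative_env1",
            (False, True): "facultative_env2",
        }[(self.fusion_in_env1, self.fusion_in_env2)]
        if self.label != expected:
            raise ValueError("label inconsistent with per-environment booleans")


def plastic_flow(start: PlasticState, params_env1: ADParams,
                 params_env2: ADParams, **flow_kwargs
                 ) -> tuple[FlowResult, FlowResult]:
    """Adaptive-dynamics trajectories of both environments' trait pairs.

    The two flows are autonomous and decoupled; occupancy only rescales
    their speed, so endpoints do not depend on P1 (asserted by tests).
    The flow integrator already normalizes speed, which absorbs the P_i
    factors entirely; trajectories and endpoints are the contractual
    output, not tau values.
    """
    r1 = flow(ADPoint(m=start.m1, alpha=start.alpha1), params_env1,
              **flow_kwargs)
    r2 = flow(ADPoint(m=start.m2, alpha=start.alpha2), params_env2,
              **flow_kwargs)
    return r1, r2


def bet_hedging_mass(p1: float, beta1: float, beta2: float) -> float:
    """Non-plastic zero-fusion ESS under fast switching:
    ``m_BH = P1 beta1 + (1 - P1) beta2``."""
    if not 0.0 <= p1 <= 1.0:
        raise ValueError("P1 must lie in [0, 1]")
    return p1 * beta1 + (1.0 - p1) * beta2


def saddle_mass(beta: float, C: float) -> float:
    """Interior-saddle mass ``-beta / (2 ln(1-C))``; on the facultative cost
    band this is the axis boundary of the zero-fusion basin as ET grows."""
    if not 0.0 < C < 1.0:
        raise ValueError("C must lie in (0, 1)")
    return -beta / (2.0 * math.log(1.0 - C))


def _in_basin(m0: float, beta: float, C: float) -> bool:
    """Large-ET basin test: m0 in the zero-fusion basin iff it sits at or
    above the interior-saddle mass (ties conservatively 'within basin')."""
    return m0 >= saddle_mass(beta, C) - TIE_TOL


def facultative_condition_adapted(beta1: float, beta2: float, C: float) -> bool:
    """Fusion evolves in environment 2 from an env-1-adapted start (m0=beta1).

    Large-ET condition: ``beta2 > 2 ln(1/(1-C)) beta1``, equivalently
    m0 = beta1 lies below environment 2's interior-saddle mass.  Both forms
    are computed and must agree.
    """
    if not 0.0 < C < 1.0:
        raise ValueError("C must lie in (0, 1)")
    printed = beta2 > 2.0 * math.log(1.0 / (1.0 - C)) * beta1 + TIE_TOL
    via_saddle = not _in_basin(beta1, beta2, C)
    if printed != via_saddle:
        raise AssertionError("equivalent facultative conditions disagree")
    return printed


def _bethedged_in_basin_env1_printed(beta1: float, beta2: float, C: float,
                                     p1: float) -> bool:
    L = math.log(1.0 - C)
    rhs = beta1 * (p1 / (p1 - 1.0) + 1.0 / (2.0 * (p1 - 1.0) * L))
    return beta2 > rhs - TIE_TOL


def _bethedged_in_basin_env2_printed(beta1: float, beta2: float, C: float,
                                     p1: float) -> bool:
    L = math.log(1.0 - C)
    denom = 2.0 * (p1 - 1.0) * L - 1.0
    if denom >= 0.0:
        # the bet-hedged mass exceeds the env-2 saddle for every beta2 > 0
        return True
    return beta2 < beta1 * (2.0 * p1 * L) / denom + TIE_TOL


def facultative_conditions_bethedged(beta1: float, beta2: float, C: float,
                                     p1: float) -> FacultativeVerdict:
    """Facultative-fusion verdict from the bet-hedged start (m0 = m_BH).

    Fusion evolves in environment i exactly when m_BH falls *outside* the
    zero-fusion basin of (beta_i, 0), i.e. below the environment's
    interior-saddle mass.  Valid on the facultative cost band
    ``1 - e^{-1/2} <= C < 1 - e^{-2}`` (large-ET limit); outside the band
    the verdict falls back to the fixed-environment regime ordering
    (fusion in both environments below the band, in neither above it),
    flagged in ``conditions``.
    """
    if not 0.0 < p1 < 1.0:
        raise ValueError("P1 must lie in (0, 1)")
    m_bh = bet_hedging_mass(p1, beta1, beta2)
    conditions: dict = {"m_bh": m_bh, "C_band": (C_LOWER, C_UPPER),
                        "in_band": C_LOWER <= C < C_UPPER}
    if not conditions["in_band"]:
        fusion = C < C_LOWER
        f1, f2 = fusion, fusion
        conditions["fallback"] = "fixed-environment regime ordering"
    else:
        in1 = _in_basin(m_bh, beta1, C)
        in2 = _in_basin(m_bh, beta2, C)
        in1_printed = _bethedged_in_basin_env1_printed(beta1, beta2, C, p1)
        in2_printed = _bethedged_in_basin_env2_printed(beta1, beta2, C, p1)
        if (in1, in2) != (in1_printed, in2_printed):
            raise AssertionError(
                "closed-form basin conditions disagree with the saddle-mass "
                f"comparison: {(in1, in2)} vs {(in1_printed, in2_printed)}")
        f1, f2 = (not in1), (not in2)
        conditions["in_basin_env1"] = in1
        conditions["in_basin_env2"] = in2
    label = {(True, True): "both", (False, False): "neither",
             (True, False): "facultative_env1",
             (False, True): "facultative_env2"}[(f1, f2)]
    return FacultativeVerdict(fusion_in_env1=f1, fusion_in_env2=f2,
                              label=label, conditions=conditions)


def regime_map(beta_ratio_grid, C_grid, p1: float,
               initial_condition_mode: str = "bet_hedged",
               beta1: float = 1.0) -> pd.DataFrame:
    """Closed-form evolutionary-outcome map over (beta2/beta1, C).

    ``initial_condition_mode="adapted_env1"`` starts the population at
    environment 1's zero-fusion fixed point; ``"bet_hedged"`` at m_BH.
    Returns a long-format frame with one labelled row per grid cell.
    All labels are large-ET limits.
    """
    if initial_condition_mode not in ("adapted_env1", "bet_hedged"):
        raise ValueError(f"unknown mode {initial_condition_mode!r}")
    rows = []
    for ratio in np.asarray(beta_ratio_grid, dtype=float):
        beta2 = ratio * beta1
        for C in np.asarray(C_grid, dtype=float):
            if C < C_LOWER:
                label = "both"
            elif C >= C_UPPER:
                label = "neither"
            elif initial_condition_mode == "adapted_env1":
                fusion2 = facultative_condition_adapted(beta1, beta2, C)
                label = "facultative_env2" if fusion2 else "neither"
            else:
                label = facultative_conditions_bethedged(
                    beta1, beta2, C, p1).label
            rows.append({"beta2_over_beta1": float(ratio), "C": float(C),
                         "P1": p1, "mode": initial_condition_mode,
                         "label": label})
    return pd.DataFrame(rows)
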