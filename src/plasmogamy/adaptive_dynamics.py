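"""Closed-form adaptive dynamics of (m, alpha) in a fixed environment.

Under rare small-effect mutations the population-mean traits follow the
gradient flow

    dm/dtau     = Hm(m, alpha; beta, C)
    dalpha/dtau = Halpha(m, alpha; beta, C)   clamped to alpha >= 0,

with selection gradients (K = (1-C) e^{beta/(2m)}, the cost-discounted
survival advantage of a same-size fused pair):

    Hm = -[4m(m - beta) + E alpha T K (4m - beta)] / [4 m^2 (m + E alpha T K)]
    Halpha = -m (1 - K) ln(1 + E alpha T / m) / [2 alpha (E alpha T K + m)]

On the alpha = 0 boundary the flow reduces to dm/dtau = (beta - m)/m^2 and
Halpha has the finite limit (K - 1) E T / (2 m).  The phase portrait is
organised by three structures: a boundary fixed point at (beta, 0), an
attracting invariant manifold m = beta/4 as alpha -> infinity (obligate
fusion), and an interior fixed point at m* = -beta / (2 ln(1-C)) that is a
saddle on the cost band 1 - e^{-1/2} < C < 1 - e^{-2}.  The saddle's stable
manifold (separatrix) bounds the basin of the zero-fusion state; the cost
C_Base at which it reaches the origin is the threshold beyond which the
whole alpha = 0 axis flows to zero fusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .survival import threshold_survival

__all__ = [
    "ADParams",
    "ADPoint",
    "FixedPointReport",
    "RegimeClassification",
    "FlowResult",
    "gradient_m",
    "gradient_alpha",
    "flow",
    "boundary_fixed_point",
    "interior_fixed_point",
    "classify_regime",
    "c_base",
    "separatrix",
    "axis_basin_boundary",
    "threshold_linear_max_cost",
    "C_LOWER",
    "C_UPPER",
]

#: transcritical bifurcation costs: interior alpha* crosses 0 at C_LOWER,
#: interior m* crosses beta/4 at C_UPPER.
C_LOWER = 1.0 - math.exp(-0.5)
C_UPPER = 1.0 - math.exp(-2.0)


@dataclass(frozen=True)
class ADParams:
    """Parameters of the adaptive-dynamics flow (E and T enter only as ET)."""

    beta: float
    C: float
    E: float = 100.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError("C must lie in [0, 1]")
        if not self.E > 0 or self.T < 0:
            raise ValueError("E must be > 0 and T >= 0")

    @property
    def ET(self) -> float:
        return self.E * self.T


@dataclass(frozen=True)
class ADPoint:
    m: float
    alpha: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.m > 0 or self.alpha < 0:
            raise ValueError("admissible region is m > 0, alpha >= 0")


@dataclass(frozen=True)
class FixedPointReport:
    location: tuple[float, float]
    kind: Literal["boundary", "interior", "asymptotic_manifold"]
    stability: Literal["stable", "saddle", "unstable", "nonphysical"]
    eigenvalues: tuple[float, float]


@dataclass(frozen=True)
class RegimeClassification:
    label: Literal["obligate_fusion_only", "bistable",
                   "boundary_basin_covers_axis", "zero_fusion_only"]
    thresholds: dict = field(default_factory=dict)


def _K(m, params: ADParams):
    # exponent capped: the gradients saturate at their large-K limits long
    # before, and this keeps the flow integrable near the m -> 0 edge
    return (1.0 - params.C) * np.exp(np.minimum(params.beta / (2.0 * m), 300.0))


def gradient_m(m, alpha, params: ADParams):
    """Selection gradient Hm on daughter-cell mass.  Scalar or vectorized."""
    if isinstance(m, float) and isinstance(alpha, float):
        beta = params.beta
        K = (1.0 - params.C) * math.exp(min(beta / (2.0 * m), 300.0))
        q = params.ET * alpha * K
        num = 4.0 * m * (m - beta) + q * (4.0 * m - beta)
        den = 4.0 * m**2 * (m + q)
        return -num / den
    m = np.asarray(m, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = params.beta
    K = _K(m, params)
    q = params.ET * alpha * K
    num = 4.0 * m * (m - beta) + q * (4.0 * m - beta)
    den = 4.0 * m**2 * (m + q)
    out = -num / den
    return float(out) if out.ndim == 0 else out


def gradient_alpha(m, alpha, params: ADParams):
    """Selection gradient Halpha on the fusion rate, with the analytic
    alpha -> 0 limit substituted on the boundary.  Scalar or vectorized."""
    if isinstance(m, float) and isinstance(alpha, float):
        beta, ET = params.beta, params.ET
        K = (1.0 - params.C) * math.exp(min(beta / (2.0 * m), 300.0))
        if alpha > 0.0:
            return -(m * (1.0 - K) * math.log1p(ET * alpha / m)
                     ) / (2.0 * alpha * (ET * alpha * K + m))
        return (K - 1.0) * ET / (2.0 * m)
    m = np.asarray(m, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    m, alpha = np.broadcast_arrays(m, alpha)
    beta, ET = params.beta, params.ET
    K = _K(m, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        interior = -(m * (1.0 - K) * np.log1p(ET * alpha / m)
                     ) / (2.0 * alpha * (ET * alpha * K + m))
    boundary = (K - 1.0) * ET / (2.0 * m)
    out = np.where(alpha > 0, interior, boundary)
    return float(out) if out.ndim == 0 else out


def boundary_fixed_point(params: ADParams) -> FixedPointReport:
    """The zero-fusion fixed point (m*, alpha*) = (beta, 0).

    Stable once the fusion cost exceeds 1 - e^{-1/2} (where the interior
    fixed point crosses the boundary in a transcritical bifurcation);
    below that it is a saddle, unstable against invasion by fusers.
    The reported eigenvalues are the tangential rate d/dm[(beta-m)/m^2]
    = -1/beta^2 and the transverse boundary gradient Halpha(beta, 0).
    """
    beta = params.beta
    lam_m = -1.0 / beta**2
    lam_a = gradient_alpha(beta, 0.0, params)
    stability = "stable" if params.C >= C_LOWER else "saddle"
    return FixedPointReport(location=(beta, 0.0), kind="boundary",
                            stability=stability,
                            eigenvalues=(lam_m, float(lam_a)))


def interior_fixed_point(params: ADParams, fd_step: float = 1e-6) -> FixedPointReport:
    """The interior fixed point m* = -beta/(2 ln(1-C)), alpha* from Hm = 0.

    alpha* = 4 m* (beta - m*) / [ET (4 m* - beta)], using that
    (1-C) e^{beta/(2 m*)} = 1 there.  Positive exactly on the cost band
    (1 - e^{-1/2}, 1 - e^{-2}); outside it the point is nonphysical
    (alpha* < 0).  Eigenvalues are finite differences of the (Hm, Halpha)
    field; on the physical band the point is a saddle.
    """
    C = params.C
    if C <= 0.0 or C >= 1.0:
        return FixedPointReport(location=(math.nan, math.nan), kind="interior",
                                stability="nonphysical",
                                eigenvalues=(math.nan, math.nan))
    L = math.log(1.0 - C)
    beta, ET = params.beta, params.ET
    m_star = -beta / (2.0 * L)
    denom = ET * (4.0 * m_star - beta)
    if denom == 0.0:
        return FixedPointReport(location=(m_star, math.inf), kind="interior",
                                stability="nonphysical",
                                eigenvalues=(math.nan, math.nan))
    a_star = 4.0 * m_star * (beta - m_star) / denom
    if a_star < 0.0:
        return FixedPointReport(location=(m_star, a_star), kind="interior",
                                stability="nonphysical",
                                eigenvalues=(math.nan, math.nan))
    # finite-difference Jacobian of the flow field
    h_m = fd_step * m_star
    h_a = fd_step * max(a_star, 1.0 / ET)
    J = np.empty((2, 2))
    for col, (dm, da) in enumerate(((h_m, 0.0), (0.0, h_a))):
        gp_m = gradient_m(m_star + dm, a_star + da, params)
        gm_m = gradient_m(m_star - dm, max(a_star - da, 0.0), params)
        gp_a = gradient_alpha(m_star + dm, a_star + da, params)
        gm_a = gradient_alpha(m_star - dm, max(a_star - da, 0.0), params)
        step = 2.0 * (h_m if col == 0 else h_a)
        J[0, col] = (gp_m - gm_m) / step
        J[1, col] = (gp_a - gm_a) / step
    eig = np.linalg.eigvals(J)
    eig = np.sort(eig.real)
    if eig[0] < 0 < eig[1]:
        stability = "saddle"
    elif eig[1] < 0:
        stability = "stable"
    else:
        stability = "unstable"
    return FixedPointReport(location=(m_star, a_star), kind="interior",
                            stability=stability,
                            eigenvalues=(float(eig[0]), float(eig[1])))


def c_base(ET: float, tol: float = 1e-14) -> float:
    """Critical cost at which the zero-fusion basin covers the alpha = 0 axis.

    Root (in L = ln(1 - C_Base), bracketed in (-2, -1/2)) of the linearized
    separatrix-through-origin condition

        8 (1+2L)^2 [5 + L(5+2L)] - (ET)^2 (2+L)^4 ln(6/(2+L) - 3) = 0.

    Monotone non-decreasing in ET, approaching 1 - e^{-1/2} as ET -> 0 and
    1 - e^{-2} as ET -> infinity.
    """
    if not ET > 0:
        raise ValueError("ET must be > 0")

    def g(L: float) -> float:
        first = 8.0 * (1.0 + 2.0 * L) ** 2 * (5.0 + L * (5.0 + 2.0 * L))
        second = ET**2 * (2.0 + L) ** 4 * math.log(6.0 / (2.0 + L) - 3.0)
        return first - second

    # L = -1/2 is a trivial double root shared with the lower bifurcation;
    # the interior root sits strictly between, so bracket just inside.
    a, b = -2.0 + 1e-9, -0.5 - 1e-13
    ga, gb = g(a), g(b)
    if not (ga > 0 > gb):
        raise ArithmeticError(
            f"no sign change in c_base bracket: g({a})={ga:.3g}, g({b})={gb:.3g}")
    L = brentq(g, a, b, xtol=tol, rtol=8.9e-16)
    return 1.0 - math.exp(L)


def classify_regime(params: ADParams, m0_range: tuple[float, float] | None = None
                    ) -> RegimeClassification:
    """Classify the evolutionary scenario by the cost ordering.

    C < 1-e^{-1/2}: obligate fusion is the only outcome from the axis;
    up to C_Base(ET): bistable (outcome depends on the initial mass);
    up to 1-e^{-2}: the zero-fusion basin covers the whole axis (a
    transient rise in alpha is still possible from small m0);
    beyond: zero fusion only.
    """
    CB = c_base(params.ET)
    thresholds = {"C_lower": C_LOWER, "C_base": CB, "C_upper": C_UPPER}
    C = params.C
    if C < C_LOWER:
        label = "obligate_fusion_only"
    elif C < CB:
        label = "bistable"
    elif C < C_UPPER:
        label = "boundary_basin_covers_axis"
    else:
        label = "zero_fusion_only"
    return RegimeClassification(label=label, thresholds=thresholds)


@dataclass
class FlowResult:
    """A trajectory of the adaptive-dynamics flow plus its outcome label."""

    tau: np.ndarray
    m: np.ndarray
    alpha: np.ndarray
    outcome: Literal["converged", "diverging_obligate_fusion", "inconclusive"]
    endpoint: tuple[float, float]

    @property
    def points(self) -> list[ADPoint]:
        return [ADPoint(m=mi, alpha=max(ai, 0.0), tau=ti)
                for ti, mi, ai in zip(self.tau, self.m, self.alpha)]


def flow(start: ADPoint, params: ADParams, *, tau_max: float = 1e5,
         alpha_max: float | None = None, grad_tol: float = 1e-8,
         rtol: float = 1e-10, atol: float = 1e-12,
         direction: float = 1.0) -> FlowResult:
    """Integrate the boundary-clamped gradient flow from ``start``.

    Terminates on fixed-point convergence (gradient norm below
    ``grad_tol``), on alpha exceeding ``alpha_max`` (classified as
    divergence towards the obligate-fusion manifold m = beta/4), or on
    exhausting the tau budget (outcome "inconclusive").  ``direction=-1``
    integrates backwards in evolutionary time without the boundary clamp
    (used to trace separatrices through the interior); such a trace stops
    when alpha reaches 0.
    """
    if alpha_max is None:
        alpha_max = 1e3 / params.ET

    backward = direction < 0
    sgn = -1.0 if backward else 1.0
    m_floor = 1e-9

    # The speed is normalized to v/(1+|v|): identical trajectories and fixed
    # points, but bounded velocity, which keeps integration stable where the
    # gradients blow up (m << beta).  tau is an abstract evolutionary time;
    # only the curve and its endpoint are contractual.
    def interior_rhs(t, y):
        m = max(y[0], m_floor)
        a = max(y[1], 0.0)
        dm = gradient_m(m, a, params)
        da = gradient_alpha(m, a, params)
        s = sgn / (1.0 + math.hypot(dm, da))
        return (s * dm, s * da)

    def boundary_rhs(t, y):
        m = max(y[0], m_floor)
        dm = gradient_m(m, 0.0, params)
        s = sgn / (1.0 + abs(dm))
        return (s * dm, 0.0)

    def grad_norm(y):
        m = max(y[0], m_floor)
        a = max(y[1], 0.0)
        dm = gradient_m(m, a, params)
        da = gradient_alpha(m, a, params)
        if not backward and a <= 0.0 and da < 0.0:
            da = 0.0  # clamped on the biological boundary alpha = 0
        return math.hypot(dm, da)

    def ev_converged(t, y):
        # smooth along interior segments (no clamp switch)
        m = max(y[0], m_floor)
        a = max(y[1], 0.0)
        return math.hypot(gradient_m(m, a, params),
                          gradient_alpha(m, a, params)) - grad_tol

    ev_converged.terminal = True
    ev_converged.direction = -1

    def ev_converged_boundary(t, y):
        return abs(gradient_m(max(y[0], m_floor), 0.0, params)) - grad_tol

    ev_converged_boundary.terminal = True
    ev_converged_boundary.direction = -1

    def ev_alpha_max(t, y):
        return y[1] - alpha_max

    ev_alpha_max.terminal = True
    ev_alpha_max.direction = 1

    def ev_m_floor(t, y):
        return y[0] - m_floor * 10

    ev_m_floor.terminal = True
    ev_m_floor.direction = -1

    def ev_alpha_zero(t, y):
        return y[1]

    ev_alpha_zero.terminal = True
    ev_alpha_zero.direction = -1

    def ev_leave_boundary(t, y):
        return gradient_alpha(max(y[0], m_floor), 0.0, params)

    ev_leave_boundary.terminal = True
    ev_leave_boundary.direction = 1

    taus: list[np.ndarray] = [np.array([0.0])]
    ms: list[np.ndarray] = [np.array([start.m])]
    als: list[np.ndarray] = [np.array([start.alpha])]
    t0, m_cur, a_cur = 0.0, start.m, start.alpha
    outcome = "inconclusive"
    if grad_norm((m_cur, a_cur)) < grad_tol:
        outcome = "converged"
    # integrate in segments, handing over between the interior field and the
    # clamped alpha = 0 boundary; the clamp never acts in backward tracing
    for _ in range(40):
        if outcome != "inconclusive" or t0 >= tau_max:
            break
        # event root-finding can leave alpha at a tiny positive residue
        on_boundary = (not backward and a_cur <= max(10.0 * atol, 1e-13)
                       and gradient_alpha(max(m_cur, m_floor), 0.0,
                                          params) < 0.0)
        if on_boundary:
            rhs = boundary_rhs
            events = [ev_converged_boundary, ev_m_floor, ev_leave_boundary]
            a_cur = 0.0
        else:
            rhs = interior_rhs
            events = [ev_converged, ev_alpha_max, ev_m_floor, ev_alpha_zero]
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(rhs, (t0, tau_max), [m_cur, a_cur],
                            method="LSODA", rtol=rtol, atol=atol,
                            events=events)
        taus.append(sol.t[1:])
        ms.append(sol.y[0][1:])
        als.append(np.maximum(sol.y[1][1:], 0.0))
        t0, m_cur, a_cur = float(sol.t[-1]), float(sol.y[0][-1]), \
            float(sol.y[1][-1])
        if sol.t_events[0].size:
            outcome = "converged"
        elif sol.t_events[1].size and not on_boundary:
            outcome = "diverging_obligate_fusion"
        elif (sol.t_events[1].size and on_boundary) or (
                not on_boundary and sol.t_events[2].size):
            outcome = "converged"  # hit the m floor
        elif backward and not on_boundary and sol.t_events[3].size:
            outcome = "converged"  # backward trace reached the axis
        # otherwise: boundary hand-off (alpha hit 0, or H_alpha turned
        # positive on the axis) -> next segment
    tau = np.concatenate(taus)
    m = np.concatenate(ms)
    alpha = np.concatenate(als)
    return FlowResult(tau=tau, m=m, alpha=alpha, outcome=outcome,
                      endpoint=(float(m[-1]), float(max(alpha[-1], 0.0))))


def separatrix(params: ADParams, method: str = "eigenvector", *,
               m_max: float | None = None, alpha_grid_max: float | None = None,
               n_grid: int = 101, tau_max: float = 1e4) -> np.ndarray:
    """Basin boundary of the zero-fusion fixed point, as (m, alpha) points.

    ``eigenvector``: backward-integrate the flow from the interior saddle
    along its stable eigendirections (the stable manifold *is* the
    separatrix).  ``grid``: classify forward-flow endpoints on a lattice and
    return the midpoints where the outcome changes along each mass column.
    Requires a regime in which the interior saddle exists (C above the lower
    bifurcation).
    """
    beta = params.beta
    if m_max is None:
        m_max = 2.5 * beta
    if alpha_grid_max is None:
        alpha_grid_max = 10.0 / params.ET
    report = interior_fixed_point(params)
    if method == "eigenvector":
        if report.stability != "saddle":
            raise ValueError(
                "no physical interior saddle at these parameters; "
                "see classify_regime for the phase-portrait structure")
        m_star, a_star = report.location
        # stable eigendirection of the FD Jacobian
        h_m = 1e-6 * m_star
        h_a = 1e-6 * max(a_star, 1.0 / params.ET)
        J = np.empty((2, 2))
        J[0, 0] = (gradient_m(m_star + h_m, a_star, params)
                   - gradient_m(m_star - h_m, a_star, params)) / (2 * h_m)
        J[1, 0] = (gradient_alpha(m_star + h_m, a_star, params)
                   - gradient_alpha(m_star - h_m, a_star, params)) / (2 * h_m)
        J[0, 1] = (gradient_m(m_star, a_star + h_a, params)
                   - gradient_m(m_star, max(a_star - h_a, 0.0), params)) / (2 * h_a)
        J[1, 1] = (gradient_alpha(m_star, a_star + h_a, params)
                   - gradient_alpha(m_star, max(a_star - h_a, 0.0), params)) / (2 * h_a)
        w, V = np.linalg.eig(J)
        stable = int(np.argmin(w.real))
        v = V[:, stable].real
        v /= np.hypot(*v)
        eps = 1e-6 * max(m_star, 1.0)
        pieces = []
        for s in (+1.0, -1.0):
            p0 = np.array([m_star, a_star]) + s * eps * v
            if p0[0] <= 0:
                continue
            res = flow(ADPoint(m=float(p0[0]), alpha=float(max(p0[1], 0.0))),
                       params, direction=-1.0, tau_max=tau_max,
                       alpha_max=alpha_grid_max * 10,
                       grad_tol=1e-10)
            pieces.append(np.column_stack([res.m, np.maximum(res.alpha, 0.0)]))
        if not pieces:
            return np.array([[m_star, a_star]])
        lower = pieces[-1][::-1] if len(pieces) > 1 else np.empty((0, 2))
        curve = np.vstack([lower, [[m_star, a_star]], pieces[0]])
        return curve
    if method == "grid":
        ms = np.linspace(m_max / n_grid, m_max, n_grid)
        alphas = np.linspace(0.0, alpha_grid_max, n_grid)
        boundary = []
        for m0 in ms:
            prev = None
            for a0 in alphas:
                # divergence only needs to clear the lattice, not reach the
                # asymptotic manifold: keeps classification cheap
                res = flow(ADPoint(m=float(m0), alpha=float(a0)), params,
                           tau_max=tau_max, alpha_max=4.0 * alpha_grid_max,
                           rtol=1e-8, atol=1e-10)
                label = res.outcome
                if prev is not None and label != prev[0]:
                    boundary.append((m0, 0.5 * (a0 + prev[1])))
                prev = (label, a0)
        if not boundary:
            raise ValueError(
                "entire lattice flows to a single outcome; no separatrix "
                "within the grid (see classify_regime)")
        return np.asarray(boundary)
    raise ValueError(f"unknown separatrix method {method!r}")


def axis_basin_boundary(params: ADParams, *, lo: float | None = None,
                        hi: float | None = None, iters: int = 40,
                        tau_max: float = 1e5) -> float:
    """Mass at which the separatrix meets the alpha = 0 axis.

    Found operationally, by bisecting the forward-flow outcome along the
    axis: initial masses below the intercept escape to obligate fusion,
    masses above it converge to the zero-fusion point.  Returns 0 when the
    zero-fusion basin already covers the whole axis (C >= the basin-closure
    cost; at C = C_Base the intercept is approximately the origin) and
    ``hi`` when the axis wholly escapes (C below the lower bifurcation).
    """
    beta = params.beta
    if lo is None:
        lo = 1e-4 * beta
    if hi is None:
        hi = beta

    def diverges(m0: float) -> bool:
        res = flow(ADPoint(m=m0, alpha=0.0), params, tau_max=tau_max,
                   rtol=1e-8, atol=1e-10)
        return res.outcome == "diverging_obligate_fusion"

    if not diverges(lo):
        return 0.0
    if diverges(hi):
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if diverges(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_linear_max_cost(gamma: float, m_min: float = 0.0) -> float:
    """Supremum fusion cost admitting selection for fusion under the
    threshold-linear survival family.

    The fused/unfused survival ratio S(2m)/S(m) = 1 + e^{-gamma m} is
    decreasing in m, so its supremum over admissible masses m >= m_min is
    attained at m_min, giving the ceiling C_max = 1 - 1/(1 + e^{-gamma m_min}).
    With no minimum viable size this is exactly 1/2; it vanishes as
    m_min -> infinity.
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    if m_min < 0:
        raise ValueError("m_min must be >= 0")
    return 1.0 - 1.0 / (1.0 + math.exp(-gamma * m_min))


def threshold_linear_max_cost_numeric(gamma: float, m_min: float = 0.0,
                                      m_max: float = 50.0,
                                      n: int = 20001) -> float:
    """Grid-based cross-check of :func:`threshold_linear_max_cost`.

    Scans the largest C with (1-C) S(2m)/S(m) > 1 over a mass grid.
    """
    lo = max(m_min, 1e-9)
    ms = np.linspace(lo, max(m_max, lo * 2), n)
    ratio = threshold_survival(2 * ms, gamma, m_min) / np.maximum(
        threshold_survival(ms, gamma, m_min), 1e-300)
    return float(1.0 - 1.0 / ratio.max())
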