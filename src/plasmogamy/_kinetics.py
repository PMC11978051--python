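"""Adaptive Runge-Kutta kernel for the mass-action fusion window.

During the fusion window of length ``T`` unfused cell counts obey

    dN_i/dt = - sum_j ((alpha_i + alpha_j)/2) N_i N_j

with fused-pair counts accumulating as

    dF_ij/dt = ((alpha_i + alpha_j)/2) N_i N_j   (i != j, unordered)
    dF_ii/dt = alpha_i N_i^2 / 2

The self-pair factor of 1/2 counts fused *cells* (each i-i fusion consumes
two i cells and produces one cell), which is the unique convention that
conserves cell number:  N_i(T) + 2 F_ii + sum_{j != i} F_ij = N_i(0).

The integrator is an embedded Cash-Karp 4(5) pair with standard step-size
control, compiled with numba because the simulator calls it once per growth
cycle (1e5-1e6 times per run); a SciPy solver call per cycle would dominate
the runtime by orders of magnitude.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Cash-Karp tableau
_A2 = 1.0 / 5.0
_A3 = (3.0 / 40.0, 9.0 / 40.0)
_A4 = (3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0)
_A5 = (-11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0)
_A6 = (1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
       44275.0 / 110592.0, 253.0 / 4096.0)
_B5 = (37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0, 512.0 / 1771.0)
_B4 = (2825.0 / 27648.0, 0.0, 18575.0 / 48384.0, 13525.0 / 55296.0,
       277.0 / 14336.0, 1.0 / 4.0)


@njit(cache=True)
def _rhs(y, alpha, S):
    """Time derivative of the packed state [N (S), F upper-triangle]."""
    dy = np.zeros_like(y)
    N = y[:S]
    # dN
    for i in range(S):
        acc = 0.0
        for j in range(S):
            acc += 0.5 * (alpha[i] + alpha[j]) * N[j]
        dy[i] = -N[i] * acc
    # dF, packed row-major upper triangle including diagonal
    k = S
    for i in range(S):
        for j in range(i, S):
            rate = 0.5 * (alpha[i] + alpha[j]) * N[i] * N[j]
            if i == j:
                rate *= 0.5
            dy[k] = rate
            k += 1
    return dy


@njit(cache=True)
def _integrate(y0, alpha, S, T, rtol, atol):
    """Cash-Karp 4(5) integration of the fusion window over [0, T].

    Returns (y_final, status); status 0 = ok, 1 = step-size collapse.
    """
    y = y0.copy()
    t = 0.0
    # initial step from the derivative scale (the controller refines it)
    d0 = _rhs(y, alpha, S)
    scale0 = 0.0
    for i in range(y.size):
        v = abs(d0[i]) / max(abs(y[i]), 1.0)
        if v > scale0:
            scale0 = v
    h = T if scale0 == 0.0 else min(T, 0.01 / scale0)
    if h <= 0.0:
        return y, 0
    h_min = 1e-14 * max(T, 1.0)
    h = max(h, 100.0 * h_min)
    while t < T:
        if h < h_min:
            return y, 1
        if t + h > T:
            h = T - t
        k1 = _rhs(y, alpha, S)
        k2 = _rhs(y + h * _A2 * k1, alpha, S)
        k3 = _rhs(y + h * (_A3[0] * k1 + _A3[1] * k2), alpha, S)
        k4 = _rhs(y + h * (_A4[0] * k1 + _A4[1] * k2 + _A4[2] * k3), alpha, S)
        k5 = _rhs(y + h * (_A5[0] * k1 + _A5[1] * k2 + _A5[2] * k3
                           + _A5[3] * k4), alpha, S)
        k6 = _rhs(y + h * (_A6[0] * k1 + _A6[1] * k2 + _A6[2] * k3
                           + _A6[3] * k4 + _A6[4] * k5), alpha, S)
        y5 = y + h * (_B5[0] * k1 + _B5[2] * k3 + _B5[3] * k4 + _B5[5] * k6)
        y4 = y + h * (_B4[0] * k1 + _B4[2] * k3 + _B4[3] * k4
                      + _B4[4] * k5 + _B4[5] * k6)
        err = 0.0
        for i in range(y.size):
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(y5[i] - y4[i]) / sc
            if e > err:
                err = e
        if err <= 1.0:
            t += h
            y = y5
            fac = 5.0 if err == 0.0 else min(5.0, 0.9 * err ** -0.2)
            h *= fac
        else:
            h *= max(0.1, 0.9 * err ** -0.25)
    return y, 0


def integrate_fusion_window(counts: np.ndarray, alphas: np.ndarray, T: float,
                            rtol: float = 1e-10, atol: float = 1e-12):
    """Integrate the fusion window numerically.

    Parameters
    ----------
    counts : (S,) initial unfused counts N_i(0)
    alphas : (S,) per-genotype fusion rates
    T : window duration

    Returns
    -------
    N_T : (S,) unfused counts at the end of the window
    F : (S, S) symmetric fused-cell counts; ``F[i, i]`` is the number of
        i-i fused cells, ``F[i, j]`` (i != j) the number of i-j fused cells.

    Raises
    ------
    FloatingPointError if the adaptive step collapses.
    """
    counts = np.ascontiguousarray(counts, dtype=np.float64)
    alphas = np.ascontiguousarray(alphas, dtype=np.float64)
    S = counts.size
    n_pairs = S * (S + 1) // 2
    y0 = np.zeros(S + n_pairs)
    y0[:S] = counts
    y, status = _integrate(y0, alphas, S, float(T), rtol, atol)
    if status != 0:
        raise FloatingPointError(
            "fusion-window integrator step collapse: "
            f"S={S}, T={T}, max alpha*N0={np.max(alphas) * counts.sum():.3g}")
    N_T = y[:S]
    F = np.zeros((S, S))
    iu = np.triu_indices(S)
    F[iu] = y[S:]
    F = F + F.T - np.diag(np.diag(F))
    return N_T, F
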