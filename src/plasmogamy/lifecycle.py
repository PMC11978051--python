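"""One deterministic growth cycle for a multi-genotype population.

A growth cycle consists of: binary fission into daughter cells (genotype i
contributes ``N_i(0) = f_i E / m_i`` daughters), a mass-action fusion window
of duration ``T``, mass-dependent survival of unfused (at mass ``m_i``) and
fused (at mass ``m_i + m_j``, discounted by ``1 - C``) cells, and
renormalization of genotype frequencies by total surviving weight.

The population between stochastic mutation events follows these
infinite-population frequency dynamics exactly (no drift).  A
finite-difference invasion-fitness oracle built on the same cycle update is
provided for cross-checking the closed-form selection gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from ._kinetics import integrate_fusion_window
from .survival import Environment, SurvivalModel, survival

__all__ = [
    "ModelParams",
    "Genotype",
    "PlasticGenotype",
    "PopulationState",
    "FusionOutcome",
    "ExtinctionError",
    "initial_counts",
    "fuse_window",
    "cycle_update",
    "invasion_gradient_fd",
]

FREQ_TOL = 1e-12


class ExtinctionError(RuntimeError):
    """Raised when a cycle leaves zero surviving weight (all cells die)."""


@dataclass(frozen=True)
class ModelParams:
    """Ecological parameters of the growth cycle.

    E : total population mass (sets the carrying capacity).
    T : duration of the fusion window.
    C : fusion cost in [0, 1]; fraction of the fused-cell contribution lost
        (fusion failure, hindered growth and failed segregation are all
        equivalent to this single multiplicative factor at the frequency
        level).
    """

    E: float = 100.0
    T: float = 1.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be > 0, got {self.E}")
        if self.T < 0:
            raise ValueError(f"T must be >= 0, got {self.T}")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"C must lie in [0, 1], got {self.C}")

    @property
    def ET(self) -> float:
        return self.E * self.T


@dataclass(frozen=True)
class Genotype:
    """A non-plastic genotype: daughter-cell mass ``m`` and fusion rate ``alpha``."""

    m: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")

    def active(self, env_index: int = 0) -> tuple[float, float]:
        return self.m, self.alpha

    @property
    def traits(self) -> tuple[float, ...]:
        return (self.m, self.alpha)


@dataclass(frozen=True)
class PlasticGenotype:
    """A plastic genotype expressing a different (m, alpha) pair per environment."""

    m1: float
    alpha1: float
    m2: float
    alpha2: float

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0):
            raise ValueError("masses must be > 0")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("fusion rates must be >= 0")

    def active(self, env_index: int = 0) -> tuple[float, float]:
        return (self.m1, self.alpha1) if env_index == 0 else (self.m2, self.alpha2)

    @property
    def traits(self) -> tuple[float, ...]:
        return (self.m1, self.alpha1, self.m2, self.alpha2)


AnyGenotype = Union[Genotype, PlasticGenotype]


class PopulationState:
    """An ordered collection of genotypes with frequencies summing to 1."""

    def __init__(self, genotypes: Sequence[AnyGenotype],
                 frequencies: Sequence[float]):
        self.genotypes = list(genotypes)
        freqs = np.asarray(frequencies, dtype=float)
        if len(self.genotypes) != freqs.size:
            raise ValueError("genotypes and frequencies differ in length")
        if np.any(freqs < 0):
            raise ValueError("frequencies must be >= 0")
        total = freqs.sum()
        if abs(total - 1.0) > FREQ_TOL:
            raise ValueError(f"frequencies must sum to 1 (got {total!r})")
        self.frequencies = freqs / total

    @staticmethod
    def monomorphic(genotype: AnyGenotype) -> "PopulationState":
        return PopulationState([genotype], [1.0])

    def __len__(self) -> int:
        return len(self.genotypes)

    def active_traits(self, env_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of the environment-active (m, alpha) of every genotype."""
        pairs = [g.active(env_index) for g in self.genotypes]
        m = np.array([p[0] for p in pairs])
        alpha = np.array([p[1] for p in pairs])
        return m, alpha

    def mean_traits(self) -> dict[str, float]:
        """Frequency-weighted mean and variance of each trait axis."""
        mat = np.array([g.traits for g in self.genotypes])  # (S, n_traits)
        f = self.frequencies
        mean = f @ mat
        var = f @ (mat - mean) ** 2
        if mat.shape[1] == 2:
            names = ("m", "alpha")
        else:
            names = ("m1", "alpha1", "m2", "alpha2")
        out: dict[str, float] = {}
        for k, name in enumerate(names):
            out[f"mean_{name}"] = float(mean[k])
            out[f"var_{name}"] = float(var[k])
        return out


@dataclass
class FusionOutcome:
    """Counts at the end of the fusion window.

    ``N[i]`` is the unfused count of genotype i; ``F[i, j]`` the number of
    fused cells from an (i, j) pair (symmetric, ``F[i, i]`` counts i-i fused
    cells, each containing two i nuclei).
    """

    N: np.ndarray
    F: np.ndarray
    N0: np.ndarray

    def conservation_residual(self) -> np.ndarray:
        """Relative residual of per-genotype cell-number conservation."""
        consumed = self.N + 2.0 * np.diag(self.F) + (
            self.F.sum(axis=1) - np.diag(self.F))
        return (consumed - self.N0) / np.maximum(self.N0, 1e-300)


def initial_counts(pop: PopulationState, params: ModelParams,
                   env_index: int = 0) -> np.ndarray:
    """Daughter-cell counts at the start of the fusion window: ``f_i E / m_i``."""
    m, _ = pop.active_traits(env_index)
    return pop.frequencies * params.E / m


def fuse_window(counts: np.ndarray, alphas: np.ndarray, T: float, *,
                rtol: float = 1e-10, atol: float = 1e-12,
                method: str = "auto") -> FusionOutcome:
    """Run the mass-action fusion window for ``T`` time units.

    ``method="auto"`` uses closed forms where exact ones exist (no fusion at
    all, or a monomorphic population, for which
    ``N(T) = N0 / (1 + alpha N0 T)``); ``method="numeric"`` forces the
    adaptive RK integrator (useful for cross-validation).
    """
    counts = np.asarray(counts, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    if T < 0:
        raise ValueError("T must be >= 0")
    if np.any(counts < 0) or np.any(alphas < 0):
        raise ValueError("counts and fusion rates must be >= 0")
    S = counts.size
    if method == "auto":
        if T == 0 or not np.any(alphas * counts.sum() > 0):
            return FusionOutcome(N=counts.copy(), F=np.zeros((S, S)),
                                 N0=counts.copy())
        if S == 1:
            n0 = counts[0]
            nT = n0 / (1.0 + alphas[0] * n0 * T)
            F = np.array([[(n0 - nT) / 2.0]])
            return FusionOutcome(N=np.array([nT]), F=F, N0=counts.copy())
    elif method != "numeric":
        raise ValueError(f"unknown method {method!r}")
    N_T, F = integrate_fusion_window(counts, alphas, T, rtol=rtol, atol=atol)
    return FusionOutcome(N=N_T, F=F, N0=counts.copy())


def surviving_weights(pop: PopulationState, params: ModelParams,
                      model: SurvivalModel, env: Environment,
                      env_index: int = 0) -> tuple[np.ndarray, FusionOutcome]:
    """Per-genotype surviving daughter weight after one full cycle.

    Genotype i is credited with its surviving unfused cells plus, per
    parental nucleus, its surviving fused cells discounted by ``1 - C``:
    ``w_i = N_i(T) S(m_i) + (1-C) [2 F_ii S(2 m_i) + sum_{j!=i} F_ij S(m_i+m_j)]``.
    """
    m, alpha = pop.active_traits(env_index)
    N0 = pop.frequencies * params.E / m
    out = fuse_window(N0, alpha, params.T)
    S_unfused = np.asarray(survival(model, m, env))
    w = out.N * S_unfused
    if np.any(out.F > 0):
        pair_mass = m[:, None] + m[None, :]
        S_fused = np.asarray(survival(model, pair_mass, env))
        contrib = out.F * S_fused
        # per-nucleus credit: diagonal counts twice for its single parent
        w = w + (1.0 - params.C) * (contrib.sum(axis=1) + np.diag(contrib))
    return w, out


def cycle_update(pop: PopulationState, params: ModelParams,
                 model: SurvivalModel, env: Environment, env_index: int = 0,
                 return_info: bool = False):
    """Apply one deterministic growth cycle and renormalize frequencies.

    With every fusion rate at zero this reduces exactly to the fission-only
    frequency update ``f_i' prop. to (f_i E / m_i) S(m_i)``.  Raises
    :class:`ExtinctionError` when no weight survives.
    """
    w, out = surviving_weights(pop, params, model, env, env_index)
    total = w.sum()
    if not total > 0.0:
        raise ExtinctionError(
            "population extinct: zero surviving weight this cycle")
    new = PopulationState(pop.genotypes, w / total)
    if return_info:
        info = {
            "survival_fraction": float(total / out.N0.sum()),
            "fusion_outcome": out,
        }
        return new, info
    return new


def invasion_gradient_fd(resident: Genotype, trait: str, params: ModelParams,
                         model: SurvivalModel, env: Environment,
                         h: float | None = None, eps: float = 1e-6) -> float:
    """Finite-difference invasion-fitness gradient at a monomorphic resident.

    Runs the full cycle update with a rare mutant (frequency ``eps``) whose
    ``trait`` ("m" or "alpha") is perturbed by ``+/- h`` and differences the
    log per-cycle growth ratio of mutant over resident.  Serves as an
    independent numerical oracle for the closed-form selection gradients:
    signs and zero crossings must agree.
    """
    if trait not in ("m", "alpha"):
        raise ValueError("trait must be 'm' or 'alpha'")
    base = getattr(resident, trait)
    if h is None:
        h = 1e-5 * max(abs(base), 1e-2)
    if h <= 0 or not 0 < eps < 0.5:
        raise ValueError("degenerate finite-difference configuration")

    def log_growth(value: float) -> float:
        if trait == "m":
            mutant = Genotype(m=value, alpha=resident.alpha)
        else:
            mutant = Genotype(m=resident.m, alpha=value)
        pop = PopulationState([resident, mutant], [1.0 - eps, eps])
        w, _ = surviving_weights(pop, params, model, env)
        if not (w[0] > 0 and w[1] > 0):
            raise ExtinctionError("zero surviving weight in invasion oracle")
        # per-capita (per unit frequency) growth of mutant relative to resident
        return float(np.log((w[1] / eps) / (w[0] / (1.0 - eps))))

    lo = base - h
    if trait == "alpha" and lo < 0:
        # one-sided difference at the alpha = 0 boundary
        return (log_growth(base + h) - log_growth(base)) / h
    if trait == "m" and lo <= 0:
        raise ValueError("finite-difference step crosses m = 0")
    return (log_growth(base + h) - log_growth(lo)) / (2.0 * h)
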