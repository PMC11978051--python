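"""Stochastic evolutionary simulation under mutation-selection balance.

Between stochastic events the population follows the deterministic
growth-cycle frequency dynamics of :mod:`plasmogamy.lifecycle`.  Stochastic
events are scheduled with geometrically distributed waiting times over
discrete growth cycles (the discrete-time analogue of a Gillespie scheme):

* mutation events, at rate ``mu`` per trait and cycle: an ancestral
  genotype is drawn with probability equal to its frequency, one trait is
  perturbed by ``+/- delta`` with equal probability, and the mutant is
  seeded at a small frequency taken from its ancestor;
* environment switches, either at pre-scheduled cycles or via a discrete
  telegraph process with geometric residence times.

A cloud of genotypes is maintained around the favoured trait value
(mutation-selection balance); genotypes falling below a pruning frequency
are dropped.  Trajectories record frequency-weighted trait means per cycle,
from which evolutionarily stable strategies are estimated by time
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .lifecycle import (AnyGenotype, ExtinctionError, Genotype, ModelParams,
                        PlasticGenotype, PopulationState, cycle_update)
from .survival import Environment, EnvironmentSchedule, SurvivalModel

__all__ = [
    "MutationParams",
    "TrajectoryRecord",
    "SimulationResult",
    "run_simulation",
    "mutate",
    "environment_step",
    "estimate_ess",
]

MAX_GENOTYPES = 1000
TRAIT_MATCH_TOL = 1e-12


@dataclass(frozen=True)
class MutationParams:
    """Mutation process parameters (rates per growth cycle).

    ``mu`` is the mutation rate per trait; ``delta_m``/``delta_alpha`` the
    fixed mutational step sizes; genotypes below ``prune_threshold`` are
    dropped; proposals below ``m_floor`` (mass) or 0 (fusion rate) are
    discarded with the event consumed, so boundary traits are not biased by
    reflection.
    """

    mu: float = 0.01
    delta_m: float = 0.02
    delta_alpha: float = 0.02
    prune_threshold: float = 1e-6
    m_floor: float = 1e-3
    seed_frequency: float = 1e-3

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if not (self.delta_m > 0 and self.delta_alpha > 0):
            raise ValueError("mutation steps must be > 0")
        if not 0.0 <= self.prune_threshold <= 1e-3:
            raise ValueError("prune_threshold must lie in [0, 1e-3]")
        if not self.m_floor > 0:
            raise ValueError("m_floor must be > 0")
        if not 0 < self.seed_frequency <= 1e-2:
            raise ValueError("seed_frequency must lie in (0, 1e-2]")


@dataclass
class TrajectoryRecord:
    """Per-cycle summary rows of a simulation run."""

    data: pd.DataFrame
    plastic: bool = False

    def __post_init__(self) -> None:
        cyc = self.data["cycle"].to_numpy()
        if cyc.size and np.any(np.diff(cyc) <= 0):
            raise ValueError("cycle indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SimulationResult:
    trajectory: TrajectoryRecord
    final_population: PopulationState
    status: str  # "completed" | "extinct" | "alpha_threshold"
    n_mutation_events: int
    mutation_event_cycles: np.ndarray


def _mutable_traits(plastic: bool, pin_alpha: bool) -> list[str]:
    if plastic:
        return ["m1", "m2"] if pin_alpha else ["m1", "alpha1", "m2", "alpha2"]
    return ["m"] if pin_alpha else ["m", "alpha"]


def _perturb(genotype: AnyGenotype, trait: str, step: float,
             mutation: MutationParams) -> Optional[AnyGenotype]:
    value = getattr(genotype, trait) + step
    if trait.startswith("m"):
        if value < mutation.m_floor:
            return None
    elif value < 0.0:
        return None
    return replace(genotype, **{trait: value})


def mutate(pop: PopulationState, mutation: MutationParams, trait: str,
           rng: np.random.Generator) -> PopulationState:
    """Apply one mutation event on ``trait`` and return the new population.

    The ancestor is drawn with probability equal to its frequency; the
    mutant gets the trait shifted by one step, sign chosen with equal
    probability, and is seeded at ``min(seed_frequency, f_ancestor/2)``
    transferred from the ancestor.  Inadmissible proposals (negative fusion
    rate, mass below the floor) are discarded: the event is consumed but
    the population is returned unchanged.  Coincident genotypes are merged.
    """
    idx = int(rng.choice(len(pop), p=pop.frequencies))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    step = mutation.delta_m if trait.startswith("m") else mutation.delta_alpha
    mutant = _perturb(pop.genotypes[idx], trait, sign * step, mutation)
    if mutant is None:
        return pop
    f = pop.frequencies.copy()
    seed = min(mutation.seed_frequency, f[idx] / 2.0)
    f[idx] -= seed
    # merge with an existing coincident genotype if any
    for j, g in enumerate(pop.genotypes):
        if all(abs(a - b) <= TRAIT_MATCH_TOL
               for a, b in zip(g.traits, mutant.traits)):
            f[j] += seed
            return PopulationState(pop.genotypes, f / f.sum())
    genotypes = pop.genotypes + [mutant]
    if len(genotypes) > MAX_GENOTYPES:
        raise RuntimeError(
            f"more than {MAX_GENOTYPES} concurrent genotypes; "
            "prune_threshold is too small for these parameters")
    f = np.append(f, seed)
    return PopulationState(genotypes, f / f.sum())


def _prune(pop: PopulationState, threshold: float) -> PopulationState:
    keep = pop.frequencies >= threshold
    if keep.all():
        return pop
    if not keep.any():
        keep[int(np.argmax(pop.frequencies))] = True
    genotypes = [g for g, k in zip(pop.genotypes, keep) if k]
    f = pop.frequencies[keep]
    return PopulationState(genotypes, f / f.sum())


def environment_step(schedule: EnvironmentSchedule, cycle: int,
                     current_index: int, rng: np.random.Generator) -> int:
    """Environment index active for this cycle, given the previous index.

    Fixed schedules never switch; scheduled ones toggle at the listed
    cycles; telegraph schedules switch with per-cycle probability
    ``lambda_12`` / ``lambda_21`` (geometric residence times).
    """
    if schedule.mode == "fixed":
        return 0
    if schedule.mode == "scheduled":
        n_switches = sum(1 for c in schedule.switch_cycles if c <= cycle)
        return n_switches % 2
    lam = schedule.lambda_12 if current_index == 0 else schedule.lambda_21
    if rng.random() < lam:
        return 1 - current_index
    return current_index


def run_simulation(initial: AnyGenotype, params: ModelParams,
                   model: SurvivalModel, schedule: EnvironmentSchedule,
                   mutation: MutationParams, n_cycles: int, seed: int, *,
                   pin_alpha: bool = False, record_every: int = 1,
                   alpha_stop: float | None = None) -> SimulationResult:
    """Run the stochastic evolutionary simulation for ``n_cycles`` cycles.

    Identical ``(arguments, seed)`` produce an identical trajectory.
    ``pin_alpha`` freezes every fusion-rate trait at its initial value
    (no alpha mutations), modelling a population without the machinery for
    fusion.  ``alpha_stop`` optionally terminates the run early once the
    mean active fusion rate exceeds the given value (used to classify runs
    that escape towards obligate fusion without simulating the divergence).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    plastic = isinstance(initial, PlasticGenotype)
    traits = _mutable_traits(plastic, pin_alpha)
    total_rate = min(1.0, mutation.mu * len(traits))
    pop = PopulationState.monomorphic(initial)

    next_mutation = int(rng.geometric(total_rate))
    mutation_cycles: list[int] = []
    env_index = 0

    n_rows = (n_cycles + record_every - 1) // record_every
    trait_names = ("m1", "alpha1", "m2", "alpha2") if plastic else ("m", "alpha")
    n_cols = 4 + 2 * len(trait_names) + 2
    buf = np.empty((n_rows, n_cols))
    row = 0
    status = "completed"

    for cycle in range(n_cycles):
        env_index = environment_step(schedule, cycle, env_index, rng)
        env = schedule.environments[env_index if len(schedule.environments) > 1
                                    else 0]
        if cycle == next_mutation:
            pop = mutate(pop, mutation, traits[int(rng.integers(len(traits)))],
                         rng)
            mutation_cycles.append(cycle)
            next_mutation = cycle + int(rng.geometric(total_rate))
        try:
            pop, info = cycle_update(pop, params, model, env, env_index,
                                     return_info=True)
        except ExtinctionError:
            status = "extinct"
            break
        pop = _prune(pop, mutation.prune_threshold)
        if cycle % record_every == 0:
            stats = pop.mean_traits()
            m_act, a_act = pop.active_traits(env_index)
            f = pop.frequencies
            rec = [cycle, env_index, len(pop)]
            for name in trait_names:
                rec.append(stats[f"mean_{name}"])
                rec.append(stats[f"var_{name}"])
            rec.extend([float(f @ m_act), float(f @ a_act),
                        info["survival_fraction"]])
            buf[row, :] = rec
            row += 1
        if alpha_stop is not None:
            _, a_act = pop.active_traits(env_index)
            if float(pop.frequencies @ a_act) >= alpha_stop:
                status = "alpha_threshold"
                break

    buf = buf[:row]
    cols = ["cycle", "env", "n_genotypes"]
    for name in trait_names:
        cols.extend([f"mean_{name}", f"var_{name}"])
    cols.extend(["mean_m_active", "mean_alpha_active", "survival_fraction"])
    df = pd.DataFrame(buf, columns=cols)
    df["cycle"] = df["cycle"].astype(int)
    df["env"] = df["env"].astype(int)
    df["n_genotypes"] = df["n_genotypes"].astype(int)
    if not plastic:
        # for non-plastic runs the active traits equal the genotype traits
        df = df.drop(columns=["mean_m_active", "mean_alpha_active"])
    trajectory = TrajectoryRecord(data=df, plastic=plastic)
    return SimulationResult(trajectory=trajectory, final_population=pop,
                            status=status,
                            n_mutation_events=len(mutation_cycles),
                            mutation_event_cycles=np.asarray(mutation_cycles))


def estimate_ess(trajectory: TrajectoryRecord,
                 burn_in_fraction: float = 0.5) -> dict[str, dict[str, float]]:
    """Time-averaged trait means over the post-burn-in window.

    Returns, per mean-trait column, the time average, the standard
    deviation over the window, and a stationarity flag: the first- and
    second-half means of the window must differ by less than two standard
    deviations (otherwise the estimate is flagged, not rejected).
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    df = trajectory.data
    start = int(len(df) * burn_in_fraction)
    window = df.iloc[start:]
    if len(window) < 2:
        raise ValueError("trajectory shorter than the burn-in window")
    out: dict[str, dict[str, float]] = {}
    half = len(window) // 2
    for col in df.columns:
        if not col.startswith("mean_"):
            continue
        x = window[col].to_numpy()
        mean, sd = float(x.mean()), float(x.std())
        drift = abs(float(x[:half].mean()) - float(x[half:].mean()))
        spread = max(float(x[:half].std()), float(x[half:].std()))
        out[col.removeprefix("mean_")] = {
            "mean": mean,
            "sd": sd,
            "stationary": bool(drift < 2.0 * spread + 1e-15),
        }
    return out
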