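"""Stochastic engine: determinism, event statistics, ESS recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmogamy import (Environment, EnvironmentSchedule, Genotype,
                        ModelParams, MutationParams, PlasticGenotype,
                        PopulationState, SurvivalModel, bet_hedging_mass,
                        environment_step, estimate_ess, mutate,
                        run_simulation)
from plasmogamy.evosim import TrajectoryRecord


class TestMutate:
    def test_mass_mutation_appends_stepped_genotype(self, default_mutation, rng):
        pop = PopulationState.monomorphic(Genotype(1.0, 0.0))
        new = mutate(pop, default_mutation, "m", rng)
        assert len(new) == 2
        assert new.genotypes[1].m in (pytest.approx(0.98), pytest.approx(1.02))
        assert new.frequencies[1] == pytest.approx(default_mutation.seed_frequency)
        assert new.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_fusion_rate_proposals_are_discarded(self, default_mutation):
        """From alpha=0, downward proposals are no-ops; upward ones appear."""
        outcomes = set()
        for seed in range(40):
            pop = PopulationState.monomorphic(Genotype(1.0, 0.0))
            new = mutate(pop, default_mutation, "alpha",
                         np.random.default_rng(seed))
            if len(new) == 1:
                assert new.frequencies == pytest.approx([1.0])
                outcomes.add("discarded")
            else:
                assert new.genotypes[1].alpha == pytest.approx(
                    default_mutation.delta_alpha)
                outcomes.add("accepted")
        assert outcomes == {"discarded", "accepted"}

    def test_mass_floor_respected(self, default_mutation):
        pop = PopulationState.monomorphic(Genotype(default_mutation.m_floor))
        for seed in range(20):
            new = mutate(pop, default_mutation, "m",
                         np.random.default_rng(seed))
            assert all(g.m >= default_mutation.m_floor for g in new.genotypes)

    def test_plastic_mutation_touches_exactly_one_trait(self, default_mutation,
                                                        rng):
        base = PlasticGenotype(1.0, 0.1, 2.0, 0.2)
        for trait in ("m1", "alpha1", "m2", "alpha2"):
            pop = PopulationState.monomorphic(base)
            new = mutate(pop, default_mutation, trait, rng)
            if len(new) == 1:
                continue  # boundary-discarded proposal
            diffs = [a != b for a, b in zip(base.traits,
                                            new.genotypes[1].traits)]
            assert sum(diffs) == 1

    def test_coincident_genotypes_merged(self, default_mutation):
        pop = PopulationState([Genotype(1.0), Genotype(1.02)], [0.9, 0.1])
        for seed in range(30):
            new = mutate(pop, default_mutation, "m",
                         np.random.default_rng(seed))
            values = [g.m for g in new.genotypes]
            assert len(values) == len(set(values))
            assert len(new) <= 3


class TestEnvironmentStep:
    def test_fixed_never_switches(self, rng):
        sch = EnvironmentSchedule.fixed(Environment(1.0))
        assert all(environment_step(sch, c, 0, rng) == 0 for c in range(100))

    def test_scheduled_switches_at_listed_cycles(self, rng):
        sch = EnvironmentSchedule.scheduled(Environment(0.5), Environment(2.2),
                                            [500])
        assert environment_step(sch, 499, 0, rng) == 0
        assert environment_step(sch, 500, 0, rng) == 1
        assert environment_step(sch, 10_000, 1, rng) == 1

    def test_symmetric_telegraph_occupancy(self, rng):
        sch = EnvironmentSchedule.telegraph(Environment(0.5), Environment(2.2),
                                            0.01, 0.01)
        env, occ = 0, 0
        n = 200_000
        for c in range(n):
            env = environment_step(sch, c, env, rng)
            occ += env == 0
        assert occ / n == pytest.approx(0.5, abs=0.02)

    def test_asymmetric_telegraph_reaches_target_occupancy(self, rng):
        sch = EnvironmentSchedule.telegraph_from_occupancy(
            Environment(0.5), Environment(2.2), p1=0.7, rate_scale=0.1)
        env, occ = 0, 0
        n = 1_000_000
        for c in range(n):
            env = environment_step(sch, c, env, rng)
            occ += env == 0
        assert occ / n == pytest.approx(0.7, abs=0.01)


class TestRunSimulation:
    def test_bitwise_deterministic_under_seed(self, vance, default_params,
                                              default_mutation):
        sch = EnvironmentSchedule.fixed(Environment(1.0))
        runs = [run_simulation(Genotype(1.0, 0.0), default_params, vance, sch,
                               default_mutation, n_cycles=2000, seed=7)
                for _ in range(2)]
        pd.testing.assert_frame_equal(runs[0].trajectory.data,
                                      runs[1].trajectory.data)
        assert runs[0].trajectory.data["mean_m"].std() > 0  # actually evolved

    def test_waiting_times_are_geometric(self, vance, default_params):
        """Inter-event times follow the geometric law of the mutation clock."""
        mut = MutationParams(mu=0.2)
        sch = EnvironmentSchedule.fixed(Environment(1.0))
        res = run_simulation(Genotype(1.0, 0.0), default_params, vance, sch,
                             mut, n_cycles=25_000, seed=11, pin_alpha=True)
        waits = np.diff(res.mutation_event_cycles)
        assert waits.size > 3000
        assert waits.mean() == pytest.approx(1 / 0.2, rel=0.1)
        # chi-square against the geometric law (binned tail)
        kmax = 25
        observed = np.bincount(np.minimum(waits, kmax + 1),
                               minlength=kmax + 2)[1:]
        probs = stats.geom(0.2).pmf(np.arange(1, kmax + 1))
        probs = np.append(probs, 1.0 - probs.sum())
        chi = stats.chisquare(observed, probs * waits.size)
        assert chi.pvalue > 0.01

    def test_fixed_environment_ess_recovers_harshness(self, vance,
                                                      default_params,
                                                      default_mutation):
        """With fusion disabled the ESS daughter mass tracks beta."""
        sch = EnvironmentSchedule.fixed(Environment(2.2, "harsh"))
        res = run_simulation(Genotype(1.8, 0.0), default_params, vance, sch,
                             default_mutation, n_cycles=50_000, seed=2,
                             pin_alpha=True, record_every=5)
        ess = estimate_ess(res.trajectory)
        assert ess["m"]["mean"] == pytest.approx(2.2, rel=0.10)
        assert ess["alpha"]["mean"] == 0.0

    def test_fast_switching_recovers_bet_hedging_mass(self, vance,
                                                      default_params,
                                                      default_mutation):
        """Telegraph switching much faster than mutation: ESS is the
        occupancy-weighted harshness (bet-hedging), not either optimum."""
        sch = EnvironmentSchedule.telegraph_from_occupancy(
            Environment(0.5, "env1"), Environment(2.2, "env2"), p1=0.7,
            rate_scale=0.5)
        res = run_simulation(Genotype(1.0, 0.0), default_params, vance, sch,
                             default_mutation, n_cycles=80_000, seed=4,
                             pin_alpha=True, record_every=5)
        ess = estimate_ess(res.trajectory)
        target = bet_hedging_mass(0.7, 0.5, 2.2)  # 1.01
        assert ess["m"]["mean"] == pytest.approx(target, rel=0.10)

    def test_fusion_replaces_size_increase_after_environment_switch(
            self, vance, default_mutation):
        """With the fusion rate evolvable at intermediate cost, a switch to
        a harsher environment selects for fusion rising from zero rather
        than for the daughter mass climbing to the new optimum."""
        sch = EnvironmentSchedule.scheduled(Environment(0.5, "benign"),
                                            Environment(2.2, "harsh"), [500])
        res = run_simulation(Genotype(1.16, 0.0),
                             ModelParams(E=100.0, T=1.0, C=0.45), vance, sch,
                             default_mutation, n_cycles=15_000, seed=11,
                             record_every=50, alpha_stop=0.25)
        df = res.trajectory.data
        before = df[df.cycle < 500]
        assert before["mean_alpha"].max() < 2 * default_mutation.delta_alpha
        final = df.iloc[-1]
        assert final["mean_alpha"] > 5 * default_mutation.delta_alpha
        assert final["mean_m"] < 2.0  # mass does not reach the new optimum

    def test_mean_trait_drifts_along_selection_gradient(self, vance,
                                                        default_params,
                                                        default_mutation):
        """Under a positive mass gradient (m < beta everywhere en route)
        checkpointed trajectory means rise essentially monotonically."""
        sch = EnvironmentSchedule.fixed(Environment(2.2))
        res = run_simulation(Genotype(1.16, 0.0), default_params, vance, sch,
                             default_mutation, n_cycles=15_000, seed=5,
                             pin_alpha=True, record_every=10)
        m = res.trajectory.data["mean_m"].to_numpy()
        checkpoints = m[:: len(m) // 20][:20]
        diffs = np.diff(checkpoints)
        assert (diffs > -2 * default_mutation.delta_m).all()
        assert checkpoints[-1] > checkpoints[0] + 0.25

    def test_extinction_is_flagged(self, default_mutation):
        model = SurvivalModel(family="threshold_linear", m_min=10.0)
        sch = EnvironmentSchedule.fixed(Environment(1.0))
        res = run_simulation(Genotype(1.0, 0.0), ModelParams(), model, sch,
                             default_mutation, n_cycles=100, seed=1)
        assert res.status == "extinct"

    def test_trajectory_cycles_strictly_increasing(self, vance, default_params,
                                                   default_mutation):
        sch = EnvironmentSchedule.fixed(Environment(1.0))
        res = run_simulation(Genotype(1.0, 0.0), default_params, vance, sch,
                             default_mutation, n_cycles=500, seed=3,
                             record_every=7)
        cyc = res.trajectory.data["cycle"].to_numpy()
        assert np.all(np.diff(cyc) > 0)


class TestEstimateEss:
    def test_constant_trajectory_gives_exact_mean_zero_sd(self):
        df = pd.DataFrame({"cycle": np.arange(10), "env": 0, "n_genotypes": 1,
                           "mean_m": 1.5, "var_m": 0.0, "mean_alpha": 0.0,
                           "var_alpha": 0.0, "survival_fraction": 0.3})
        ess = estimate_ess(TrajectoryRecord(data=df))
        assert ess["m"] == {"mean": 1.5, "sd": 0.0, "stationary": True}

    def test_drifting_trajectory_flagged_nonstationary(self):
        df = pd.DataFrame({"cycle": np.arange(100), "env": 0,
                           "n_genotypes": 1,
                           "mean_m": np.linspace(1.0, 2.0, 100),
                           "var_m": 0.0})
        ess = estimate_ess(TrajectoryRecord(data=df), burn_in_fraction=0.0)
        assert not ess["m"]["stationary"]

    def test_short_window_rejected(self):
        df = pd.DataFrame({"cycle": [0], "mean_m": [1.0]})
        with pytest.raises(ValueError):
            estimate_ess(TrajectoryRecord(data=df), burn_in_fraction=0.9)
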