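"""Facultative (stress-induced) fusion under switching environments.

First evaluates the closed-form large-ET conditions for fusion to be
selected in only the harsher environment, from both parsimonious initial
states; then runs a plastic four-trait stochastic simulation under
telegraph switching (P1=0.7) to show the prediction realized.  Takes ~15 s.
"""

from plasmogamy import (Environment, EnvironmentSchedule, ModelParams,
                        MutationParams, PlasticGenotype, SurvivalModel,
                        bet_hedging_mass, facultative_condition_adapted,
                        facultative_conditions_bethedged, run_simulation)

beta1, beta2, C, p1 = 0.5, 2.2, 0.6, 0.7

print(f"bet-hedging mass m_BH = {bet_hedging_mass(p1, beta1, beta2):.3f}")
print("env1-adapted start: fusion selected in harsh env?",
      facultative_condition_adapted(beta1, beta2, C))
verdict = facultative_conditions_bethedged(beta1, beta2, C, p1)
print("bet-hedged start verdict:", verdict.label)

schedule = EnvironmentSchedule.telegraph_from_occupancy(
    Environment(beta1, "benign"), Environment(beta2, "harsh"), p1=p1,
    rate_scale=0.05)
res = run_simulation(PlasticGenotype(beta1, 0.0, beta1, 0.0),
                     ModelParams(E=100, T=1, C=C), SurvivalModel(), schedule,
                     MutationParams(), n_cycles=30_000, seed=5,
                     record_every=100, alpha_stop=0.25)
stats = res.final_population.mean_traits()
print(f"\nafter {res.trajectory.data['cycle'].iloc[-1]} cycles "
      f"(status: {res.status}):")
print(f"  benign-environment traits: m1={stats['mean_m1']:.3f}, "
      f"alpha1={stats['mean_alpha1']:.3f}")
print(f"  harsh-environment traits:  m2={stats['mean_m2']:.3f}, "
      f"alpha2={stats['mean_alpha2']:.3f}")
print("The fusion rate expressed in the harsh environment has climbed far")
print("from zero while the benign-environment rate stays at zero: binary")
print("cell fusion evolves specifically as a stress response.")
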