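"""Cost thresholds organizing the whole model.

Prints the two transcritical bifurcation costs, the ET-dependent
basin-closure cost C_Base, and the cost ceiling under the threshold-linear
survival family with and without a minimum viable cell size.
"""

from plasmogamy import C_LOWER, C_UPPER, c_base, threshold_linear_max_cost

print(f"obligate fusion guaranteed below C = {C_LOWER:.4f} (1 - e^-1/2)")
print(f"fusion impossible to select above C = {C_UPPER:.4f} (1 - e^-2)")
print("\nbasin-closure cost C_Base(ET) between those bounds:")
for et in (0.1, 1.0, 10.0, 100.0, 1000.0):
    print(f"  ET = {et:7.1f}: C_Base = {c_base(et):.4f}")
print("denser populations / longer fusion windows (larger ET) keep fusion")
print("evolvable at higher costs.")

print("\nthreshold-linear survival, cost ceiling 1 - 1/(1 + e^(-gamma m_min)):")
for m_min in (0.0, 0.5, 2.0):
    print(f"  m_min = {m_min}: C_max = "
          f"{threshold_linear_max_cost(1.0, m_min):.4f}")
print("without a minimum viable size the fused/unfused survival ratio is")
print("capped at 2, so fusion tolerates at most a 50% cost.")
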