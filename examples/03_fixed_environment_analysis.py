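"""Adaptive dynamics in a fixed environment: fixed points, regimes, basins.

Computes the phase-portrait skeleton for a given harshness and fusion cost:
the zero-fusion fixed point (beta, 0), the interior saddle, the regime
label implied by the cost thresholds, and the basin boundary on the
alpha = 0 axis.  Then integrates two flows to show bistability.
"""

from plasmogamy import (ADParams, ADPoint, axis_basin_boundary,
                        boundary_fixed_point, c_base, classify_regime, flow,
                        interior_fixed_point)

params = ADParams(beta=1.0, C=0.6, E=100.0, T=1.0)

bd = boundary_fixed_point(params)
inter = interior_fixed_point(params)
regime = classify_regime(params)

print(f"zero-fusion fixed point: {bd.location}, {bd.stability}")
print(f"interior saddle: ({inter.location[0]:.4f}, {inter.location[1]:.4f}), "
      f"{inter.stability}, eigenvalues {tuple(round(e, 3) for e in inter.eigenvalues)}")
print(f"regime at C=0.6, ET=100: {regime.label}")
print(f"cost thresholds: lower {regime.thresholds['C_lower']:.4f}, "
      f"C_Base(ET=100) {regime.thresholds['C_base']:.4f}, "
      f"upper {regime.thresholds['C_upper']:.4f}")

intercept = axis_basin_boundary(params)
print(f"\nbasin boundary on the alpha=0 axis: m = {intercept:.4f}")
print("initial masses below this escape to obligate fusion, above it the")
print("population stays at zero fusion:")

for m0 in (0.45, 0.65):
    res = flow(ADPoint(m=m0, alpha=0.0), params)
    print(f"  flow from (m={m0}, alpha=0): {res.outcome}, "
          f"endpoint (m, alpha) = ({res.endpoint[0]:.3f}, {res.endpoint[1]:.3f})")
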