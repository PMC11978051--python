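# plasmogamy

Simulator and adaptive-dynamics toolkit for the coevolution of
daughter-cell size and binary cell-fusion rate in unicellular organisms.

## The scientific problem

In many facultatively sexual unicellular eukaryotes (e.g. *Chlamydomonas
reinhardtii*, *Schizosaccharomyces pombe*, *Tetrahymena*), sexual
reproduction begins with the fusion of two cells (plasmogamy) and is
triggered by environmental stress.  This package implements a quantitative
model of one purely physiological hypothesis for why binary cell fusion
evolves at all: larger cells survive harsh conditions better, and fusing
two small daughter cells is an alternative route to a large cell.

The life cycle is a discrete growth cycle.  A population of total mass `E`
produces daughter cells of genetically determined mass `m` (genotype `i`
makes `f_i E / m_i` daughters), the daughters may fuse pairwise during a
window of length `T` by mass action with evolvable rate `alpha`,

    dN_i/dt = - sum_j ((alpha_i + alpha_j)/2) N_i N_j,

and all cells then face mass-dependent mortality, by default the Vance
survival function

    S(m; beta) = exp(-beta / m),

where `beta` is the harshness of the environment.  Fused cells survive at
the pooled mass `m_i + m_j` but pay a fusion cost: their contribution to the
next generation is discounted by `1 - C`.  Genotype frequencies update as

    f_i'  ∝  N_i(T) S(m_i)  +  (1-C) Σ_j F_ij(T) S(m_i + m_j),

and rare mutations of small effect (`m ± δm`, `alpha ± δα`) drive evolution
under mutation–selection balance.

In the adaptive-dynamics limit the mean traits follow the selection
gradients `H_m` and `H_alpha` (closed forms in
`plasmogamy.adaptive_dynamics`).  The phase portrait is organised by a
zero-fusion fixed point at `(m*, alpha*) = (beta, 0)`, an obligate-fusion
manifold `m = beta/4` with `alpha → ∞`, and an interior saddle at
`m* = -beta / (2 ln(1-C))`.  Two transcritical bifurcations at
`C = 1 - e^{-1/2} ≈ 0.39` and `C = 1 - e^{-2} ≈ 0.86` separate four
regimes (obligate fusion / bistable / basin-covers-axis / zero fusion),
with the basin-closure cost `C_Base(ET)` computable between them.  With
two switching environments and costless phenotypic plasticity, the model
predicts *facultative* fusion: fusion evolves only in the harsher
environment for intermediate costs — stress-induced sex.

## Worked example

```python
from plasmogamy import (ADParams, boundary_fixed_point, interior_fixed_point,
                        classify_regime, c_base)

params = ADParams(beta=2.2, C=0.6, E=100.0, T=1.0)
print(boundary_fixed_point(params).location)   # (2.2, 0.0) — stable
print(interior_fixed_point(params).location)   # (1.2005, 0.0184) — saddle
print(classify_regime(params).label)           # 'bistable'
print(round(c_base(100.0), 4))                 # 0.8262
```

The boundary point `(2.2, 0.0)` is the zero-fusion ESS: daughter mass
matches the harshness.  The saddle at mass `1.2005` splits the `alpha = 0`
axis: populations with smaller daughters evolve ever-higher fusion rates,
larger ones abandon fusion.  `C_Base(ET=100) = 0.8262` is the cost above
which the zero-fusion basin swallows the whole axis.

The `examples/` directory holds one short narrative script per capability
(survival curves, a single growth cycle, fixed-environment analysis, the
environment-switch simulation, facultative fusion, cost thresholds):

```bash
python examples/03_fixed_environment_analysis.py
```

A thin CLI wraps the same library for shell use:

```bash
plasmogamy simulate --config config.yaml --out results/
plasmogamy cbase    --config config.yaml --out results/
```

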