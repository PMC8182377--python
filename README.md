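# knotfold

Quantitative biophysics of backbone-cyclized knotted proteins.

Covalently joining the N- and C-termini of a deeply trefoil-knotted
protein such as YibK turns an "open" protein knot into a true
mathematical knot, and changes its folding thermodynamics, denatured-state
dynamics and polymer dimensions. `knotfold` implements the complete
quantitative analysis chain for such a study as a tested, reusable
library:

- **equilibrium** — SVD state counting of denaturation spectral series and
  three-state (N ⇌ I ⇌ D) fits, with fractional populations
  f_N = 1/(1 + K₁ + K₁K₂), K_i = exp(−(ΔG_i − m_i[D])/RT), and an optional
  Gaussian signal-loss window for aggregation of the intermediate.
- **thermal** — global two-state CD-melt fits, f_U = K/(1+K) with
  ΔG(T) = ΔH_vH(1 − T/T_m), yielding an apparent T_m.
- **kinetics** — multi-exponential trace fits, two-state chevron fits
  k_obs([D]) = k_f^{H₂O}·e^{m_f[D]/RT} + k_u^{H₂O}·e^{m_u[D]/RT}, and the
  derived quantities m_kin = m_u − m_f, β_T = −m_f/m_kin,
  ΔG_kin = RT·ln(k_f/k_u), [D]₅₀ = ΔG_kin/m_kin.
- **binding** — single-site Wiseman isotherm (exact quadratic bound
  fraction) and the bookkeeping ΔG = RT·ln K_d, TΔS = ΔH − ΔG.
- **relaxation** — ¹⁵N R₁/R₂/hetNOE extraction, reduced spectral density
  mapping to J(0), J(ω_N), J(0.87ω_H), isotropic model-free reference
  curves, and Gaussian-mixture T₁/T₂ residue profiles.
- **saxs** — iterative Guinier fits (ln I linear in q², q·R_g ≤ 1.3),
  Kratky shape classification, Flory scaling R_g = R₀N^ν, and the
  cyclic/linear Gaussian-chain ratio ⟨R_g,c²⟩/⟨R_g,l²⟩ (theory: ½).
- **knots** — KMT chain reduction, direct/radial/stochastic path closure,
  and the Alexander determinant |Δ(−1)| (1 = unknot, 3 = trefoil,
  5 = figure-eight) with per-closure voting for open chains.
- **synthdata** — seeded generators for every input class with attached
  ground truth, so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from knotfold import kinetics, saxs, knots, synthdata

# chevron-derived thermodynamics of a fast folding phase at 25 degC
d = kinetics.derive_thermo(kf0=47.6, mf=-2.87, ku0=0.036, mu=0.19)
print({k: round(v, 2) for k, v in d.items()})
# {'m_kin': 3.06, 'beta_T': 0.94, 'D50_kin': 1.39, 'dG_kin': 4.26}

# dimension ratio of a cyclized vs linear denatured chain (ideal: 0.5)
print(round(saxs.kramers_ratio(27.71, 39.26), 2))   # 0.5

# knot verdict for an open, deeply knotted backbone
chain = synthdata.gen_open_trefoil(200, trim=1)
call = knots.classify(chain, scheme="stochastic", n_closures=100, seed=3)
print(call.label, call.closure_votes)
# 3_1 {'3_1': 0.92, 'unknot': 0.08}
```

m_kin (3.06 kcal·mol⁻¹·M⁻¹) measures the total denaturant sensitivity of
the phase, β_T ≈ 0.94 says the transition state buries almost as much
surface as the native state, and ΔG_kin ≈ 4.26 kcal/mol is the phase's
equilibrium stability inferred purely from its rate constants.  The
closure votes show that ~9 of 10 random path closures of the open chain
see a trefoil — the verdict an open "knot" gets depends on how its ends
are joined.

A command-line interface mirrors the library
(`knotfold simulate|equilibrium|thermal|kinetics|binding|relax|saxs|knots|demo`);
`knotfold --seed 7 demo --outdir out/` runs every stage end-to-end on
generated data and writes a flat, diffable JSON report.

## Documentation

`docs/methods.md` describes the models, their assumptions, default
parameters, numerical choices and limitations.
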