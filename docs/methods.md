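# Methods

This note documents the models behind each `knotfold` module, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Thermodynamic conventions

All free energies are in kcal/mol with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and
a default temperature of 298.15 K (RT = 0.5925 kcal/mol). m-values carry
energy units (kcal·mol⁻¹·M⁻¹) and enter every rate or equilibrium law
divided by RT; this is the only convention under which chevron-derived
free energies obey ΔG_kin = RT·ln(k_f/k_u) with the published magnitudes.

## Equilibrium denaturation (`equilibrium`)

The three-state model is a linear scheme N ⇌ I ⇌ D with denaturant-linear
step free energies ΔG_i(D) = ΔG_i − m_i·D. Populations are evaluated in
log space against the largest Boltzmann exponent, so no overflow occurs
at any denaturant concentration; they sum to 1 to ≤1e−12 by construction.

State counting uses SVD of the wavelength × condition matrix. Because no
standard threshold exists, the default rank rule counts singular values
exceeding 3× the median of the trailing half of the spectrum — a noise-floor
estimate that is robust for the 41-condition series this package targets —
and is replaceable by any callable.

Fitting follows an SVD-then-fit strategy: the model is fitted to the
leading `n_states` singular-value-scaled amplitude vectors rather than to
the raw matrix. This conditions the problem (the discarded components are
noise by the rank decision) and makes the fit independent of the
wavelength dimension. Per-state spectral amplitudes, linear in [D]
(baselines), are solved by linear least squares inside the nonlinear
search (variable projection), leaving only (ΔG₁, m₁, ΔG₂, m₂) and the
optional loss window as nonlinear parameters.

Aggregation-induced fluorescence loss is modelled as a multiplicative
window 1 − A·exp(−(D−μ)²/2σ²) on the total signal; the lost fraction is
reported as an "aggregated" population for plotting. With `loss="auto"`
the window is accepted only if it improves a corrected-AIC comparison
against the loss-free nested fit by more than 2; otherwise a
zero-amplitude window is reported. Because the window is partially
degenerate with the first transition, the forced fit is multi-started
over five window centres spanning the concentration range.

Dimer-linked equilibria are deliberately ignored; the model treats the
protein as an effective monomer.

## Thermal melts (`thermal`)

Two-state Gibbs–Helmholtz with ΔCp = 0: ΔG(T) = ΔH_vH(1 − T/T_m). Only an
apparent T_m is claimed — thermal unfolding of aggregation-prone knotted
proteins is typically irreversible, and ΔCp is unidentifiable from a
single melt. The global fit shares (T_m, ΔH_vH) across all wavelengths
with per-wavelength linear-in-T folded/unfolded baselines, again solved
by variable projection; the baseline coordinate is centred to keep the
linear system well conditioned.

## Folding kinetics (`kinetics`)

Traces are fitted to offset + Σ aᵢ·exp(−kᵢt), nonlinear only in ln kᵢ
(amplitudes by linear least squares). Automatic model selection compares
1–4 exponentials by corrected AIC and skips fits whose rates are
separated by less than 1.5× (flagged degenerate). Chevron fits run in
ln k space with equal weights, because observed rates span seven orders
of magnitude; bounds enforce the sign convention m_f ≤ 0 ≤ m_u. The
`fix_mu_zero` flag reproduces the convention used when an unfolding arm
shows no denaturant dependence, which forces β_T = 1 exactly.

The derived quantities are m_kin = m_u − m_f, β_T = −m_f/m_kin,
ΔG_kin = RT·ln(k_f/k_u), and the standard midpoint definition
[D]₅₀ = ΔG_kin/m_kin. Stopped-flow dead-time effects and sequential
three-state global fits are out of scope; phases are fitted
independently.

## Binding (`binding`)

The single-site isotherm uses the exact quadratic solution for the bound
concentration; per-injection heats are increments of V_cell·ΔH·[MX].
Input is integrated heats (thermogram peak integration is upstream of
this package). Displaced-volume corrections are not modelled; the
generator and the fitter share this simplification, and a brute-force
root-bracketing equilibrium solver serves as the independent oracle for
the closed form. Heats in kcal for micromolar samples are ~1e−8 in
magnitude, so fit residuals are normalised by the largest heat to keep
gradient-based termination criteria meaningful.

## ¹⁵N relaxation (`relaxation`)

Forward rates use the standard dipolar + CSA expressions with
r_NH = 1.02 Å, Δσ = −160 ppm and a default field corresponding to an
850 MHz ¹H frequency, on the isotropic model-free spectral density
J(ω) = (2/5)[S²τ_m/(1+(ωτ_m)²) + (1−S²)τ′/(1+(ωτ′)²)]. The ¹⁵N
gyromagnetic ratio is carried with its negative sign, which makes the
NOE expressions and the reduced-mapping σ_NH come out with the correct
signs without special-casing.

Reduced spectral density mapping inverts (R₁, R₂, NOE) into J(0), J(ω_N)
and an effective J(0.87ω_H) under the assumption that J is flat near the
proton frequency; round-tripping forward rates through the mapping
reproduces J(0) and J(ω_N) to within the ~2% error of that reduction
across S² ∈ [0.3, 1], τ_m ∈ [1, 15] ns. The axis convention for quoting
the order parameter (S vs S²) differs between studies; reference curves
take S² and callers may square as needed.

T₁/T₂ residue profiles are fitted to baseline + sum of Gaussians in
residue index, nonlinear only in centres and widths. Component count is
selected by BIC (k = 0…4): with ~100 residues, AIC-type penalties admit
spurious low-amplitude components, while BIC selects 0 components for
flat ("linear-like") profiles and the correct count for seeded clusters.
An exchange term R_ex on R₂ generates "cyclized-like" synthetic data:
clusters of exchange-broadened residues lower the mean T₂ and make the
T₁/T₂ profile multi-modal — the qualitative signature of conformational
exchange imposed by backbone cyclization — without claiming any specific
measured T₂ values.

## SAXS (`saxs`)

Guinier fits are weighted linear fits of ln I vs q² starting at the
lowest usable q. The window first grows/shrinks to the self-consistent
q_max·R_g ≤ 1.3 and is then refined against truncation bias: while
shrinking the window moves the fitted R_g by more than its statistical
error (plus a 0.5% floor), curvature from outside the strict Guinier
regime is contaminating the fit and the window shrinks. On noiseless
synthetic profiles this recovers a sphere's R_g to <1% and a Debye
coil's to <2%; with the full q_max·R_g = 1.3 window and no refinement
the coil bias would be ~−6%, which is why the refinement exists. On
noisy data the statistical-error criterion stops the shrinkage early, so
a few-percent negative bias remains for coils — inherent to Guinier
analysis of coil scattering.

Kratky classification smooths q²I with a short moving average and calls
"bell" when an interior maximum is followed by a ≥20% decay. The
cyclic/linear ratio is reported as (R_g,c/R_g,l)² against the
ideal-chain reference ½; single measured R_g values stand in for
ensemble means. The Monte-Carlo oracle builds linear Gaussian chains as
cumulative Gaussian steps and rings as Brownian bridges.

The Flory scaling law R_g = R₀·N^ν ships with ν = 3/5 (good solvent) and
a configurable prefactor; `ScalingLaw.calibrated(N*, Rg*)` pins the law
through a reference point. No particular prefactor is claimed to
reproduce any published calibration.

## Knot detection (`knots`)

Closed curves are KMT-reduced (a vertex is deleted when its spanning
triangle is pierced by no other segment — an ambient isotopy), then
projected to a plane after a seeded random rotation; degenerate
projections (near-parallel segments, vertex-grazing crossings, equal
depths, or an even determinant) trigger a retry with a new rotation.
The Alexander matrix is evaluated at t = −1 where crossing signs cancel:
each crossing contributes 2·x_over − x_under,in − x_under,out, and the
determinant of an (m−1)×(m−1) minor is computed exactly with Bareiss
fraction-free integer elimination. The determinant distinguishes
unknot (1), trefoil (3) and figure-eight (5), which is sufficient for
this package's claims; the full polynomial is out of scope.

Open chains are closed before any reduction. This ordering is essential:
KMT on an open arc is an isotopy of the arc alone and may sweep through
the region a later closure segment would occupy, silently changing the
closed-curve topology (straightening a deeply knotted open chain
entirely, in the worst case). Closure schemes: `direct` (straight
segment), `radial` (termini pushed far out along centroid rays), and
`stochastic` (n closures through points uniform on a sphere of 100× the
chain's extent, majority vote with per-label vote fractions reported).
The vote split is the quantitative face of the statement that whether an
open chain "is knotted" depends on the closure algorithm.

PDB/mmCIF input takes one chain's Cα trace (altloc A) via gemmi; gaps of
≤3 residues are bridged by linear interpolation with a warning, larger
gaps raise.

## Synthetic data (`synthdata`)

Generators draw from exactly the forward models above, attach a
`GroundTruth` record, and take explicit seeds (never global state).
Noise is additive i.i.d. Gaussian on the signal; SAXS alternatively uses
σ ∝ √I. Defaults mirror a realistic study: 41 urea points 0–7 M (2.5%
linear increments), melts 25–80 °C every 2 °C, fluorescence basis bands
at 330/340/355 nm with decreasing amplitude (the red-shift and quenching
of tryptophan emission on unfolding; no published basis spectra exist,
so these are package defaults), relaxation delay sets 20–1000 ms (T₁)
and 16–256 ms (T₂), a q-range of 0.005–0.434 Å⁻¹, and a titration of 28
injections to a final titrant:site ratio of 5 (a 0.5 mM syringe into a
20 µM cell). What the generators do *not* emulate: detector images and
FIDs, instrument dead time, baseline drift, correlated noise,
dimerization linkage, and irreversibility — so passing recovery tests
demonstrate correctness of the inference machinery under the stated
noise model, not robustness to every pathology of real data.

## Known limitations

- The equilibrium loss window is only partially identifiable when it
  overlaps a transition; parameter errors widen accordingly, and the
  multi-start is a heuristic, not a guarantee of the global optimum.
- Guinier fits of coil scattering carry a negative bias at realistic
  noise (see above).
- Binding-parameter recovery at c = M/K_d ≈ 2 is intrinsically noisy;
  accuracy statements are made over replicates.
- The knot classifier assumes a single chain without self-intersections
  at projection tolerance; it does not compute knot depth, slipknots or
  knotoids.
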