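# Methods

## Model

`vdwsolv` treats a liquid as a van der Waals fluid of monoatomic
particles: each molecule owns a repulsive volume `b` and the attractive
interactions enter only as a uniform background energy. For a binary
mixture (N₁ solvent, N₂ solute particles in volume V at temperature T)
the canonical partition function is

    Q = V^(N₁+N₂)/(N₁!Λ₁^3N₁ · N₂!Λ₂^3N₂)
        · ((V − b₁N₁ − b₂N₂)/V)^(N₁+N₂)
        · exp[(√a₁·N₁ + √a₂·N₂)²/(kTV)]

i.e. free translation in the free volume plus the constant attractive
potential energy −(√a₁N₁+√a₂N₂)²/V, with a geometric-mean cross term for
unlike pairs built into the square. The Helmholtz free energy A = −kT·ln Q
(with Stirling's approximation, particle numbers continuous) yields the
solute chemical potential analytically,

    μ₂ = kT·ln(ρ₂Λ₂³) + μ₂•,

whose non-translational part μ₂• is the coupling work of a solute fixed in
the solution — the Ben-Naim standard chemical potential. The package
implements both this finite-composition form (`vdwsolv.mixture`) and its
infinite-dilution limit in closed form (`vdwsolv.core`), where

    ΔG• = −RT·ln(1−ρ₁b₁) + RT·ρ₁b₂/(1−ρ₁b₁) − 2√(a₁a₂)/v₁
        = ΔG_c + ΔG_a.

The mixture route exists to *check* the closed forms: the analytic μ₂ is
verified against central finite differences of A, and μ₂• at mole fraction
x₂ = 10⁻⁹ against ΔG•, in the test suite.

Assumptions inherited from the model: monoatomic species (no internal
degrees of freedom), a and b temperature-independent, free volume treated
as uniformly accessible. The last point is why the model is only
qualitatively correct: it neglects the division of free volume into
molecular-sized cavities, so cavity work is underestimated relative to
scaled particle theory or simulation. No quantitative agreement with
experimental solvation data is claimed, and none should be expected.

## Parameters and units

| parameter | meaning | unit | default / convention |
|---|---|---|---|
| σ | effective hard-sphere diameter | Å | solute default 4.0 (xenon) |
| b | repulsive volume per molecule | Å³ | (πσ³/6)/0.64, random close packing |
| v₁ | solvent molar volume | cm³ mol⁻¹ | experimental, at 298.15 K |
| α_P | isobaric expansion coefficient | K⁻¹ | experimental, held constant in T |
| a | attraction parameter (molar) | kJ cm³ mol⁻² | user input; none for real liquids |
| T | temperature | K | 298.15 |

Energies are reported in kJ mol⁻¹, entropies in J K⁻¹ mol⁻¹. Constants are
CODATA: R = 8.314462618 J mol⁻¹ K⁻¹, N_Av = 6.02214076×10²³ mol⁻¹,
1 atm = 101325 Pa. All unit conversions live in `vdwsolv.constants`;
dimensionless packing products are formed as ρ₁b = N_Av·b[Å³]/(v₁[cm³ mol⁻¹]·10²⁴).
Attraction parameters are carried in molar units and converted internally
to per-molecule J Å³ via a_molar = N_Av²·a_molecular; the geometric-mean
cross term √(a₁a₂) is part of the model, not a user choice.

The 0.64 random-close-packing convention is used for every species,
solvent and solute alike; the tabulated b₁ values agree with (πσ³/6)/0.64
to 0.1 Å³ and this is enforced as a dataset invariant.

## Temperature model

α_P is treated as constant, so v₁(T) = v₁(T_ref)·exp(α_P·(T−T_ref)).
This is the unique choice under which the closed-form ΔS and ΔH
expressions are the *exact* temperature derivatives of ΔG (−∂ΔG/∂T and
−T²·∂(ΔG/T)/∂T), which lets the derivative oracle tests run at a relative
tolerance of 10⁻⁶ with a 10⁻³ K central-difference step rather than a
loose band. Negative α_P (water below 4 °C) is accepted with a logged
warning; the formulas remain valid.

Enthalpy–entropy compensation is exact and tested as such: at the
reference temperature ΔG_c is bit-identical under any change of α_P,
ΔH_c is linear and homogeneous in α_P, and T·ΔS_nx = ΔH_c to machine
precision. Pressure never enters numerically: the second cavity term is
interpreted (and tested) as kinetic pressure RT/(v₁−b₁) times the solute
volume, with the kinetic term — not the full equation-of-state pressure —
chosen because the pressure–volume reading of that term is approximate
(`kinetic_pressure`).

## Built-in dataset and comparison modes

`vdwsolv.data` ships the eight-liquid reference dataset (water, methanol,
ethanol, CCl₄, n-hexane, n-decane, c-hexane, benzene: σ, v₁, α_P, b₁ at
25 °C and 1 atm) together with published cavity-thermodynamics values for
a 4 Å solute. The comparison harness (`vdwsolv.report.cavity_table`)
supports two modes:

* **full** (default): recompute everything at full precision, round to the
  table's printed precision (0.1), and compare at ±0.2 kJ mol⁻¹ for
  ΔG_c/ΔH_c and ±1.2 J K⁻¹ mol⁻¹ for the entropy columns.
* **printed**: derive the entropy columns from the *published* ΔG_c and
  ΔH_c (ΔS_x = −ΔG_c/T, ΔS_nx = ΔH_c/T, each rounded to 0.1, summed to
  ΔS_c). This reproduces the published entropy columns exactly at one
  decimal, confirming they were obtained by rounding propagation from the
  energy columns; residuals up to ≈0.3 J K⁻¹ mol⁻¹ between full-precision
  entropies and the published ones are explained by this rounding.

**Known discrepancy.** The n-hexane reference row is internally
inconsistent: its published inputs (σ = 5.92 Å, v₁ = 131.62 cm³ mol⁻¹,
α_P = 1.390×10⁻³ K⁻¹) yield ΔG_c = 6.37 and ΔH_c = 8.50 kJ mol⁻¹, while
the published outputs are 6.5 and 8.8. A diameter of 5.93 Å (or
v₁ ≈ 131.0) would reproduce both outputs, suggesting a misprint in the
source values. The package computes from the stated inputs rather than
adjusting any parameter to force agreement, so the corresponding
comparison test fails for n-hexane ΔH_c and is left failing deliberately.
n-decane's ΔH_c (16.72 recomputed vs 16.5) sits exactly at the ±0.2 band
once rounded to the printed precision, which is why the comparison rounds
before applying the band.

## Synthetic fixtures

`fixture_generator(seed, n)` draws solvent/solute pairs with σ ∈ [2, 8] Å,
packing fraction ξ₁ ∈ [0.3, 0.95] (the molar volume is derived from ξ₁,
spanning loosely to very densely packed liquids), α_P ∈ [0, 2×10⁻³] K⁻¹
(the range of common liquids) and a ∈ [0, 10⁶] kJ cm³ mol⁻², with masses
spanning light gases to small organics. Generation is deterministic for a
fixed seed. These fixtures exercise the *identities* of the model —
ΔG = ΔH − TΔS per channel, entropy splits, derivative oracles,
monotonicity — over a far wider parameter range than real liquids occupy;
they do not emulate correlations present in real data (e.g. between σ,
v₁ and α_P), so passing them demonstrates internal mathematical
consistency of the implementation, not fidelity to any particular liquid.
Fidelity to the reference liquids is tested separately via the built-in
dataset. Identity and oracle tests run on 1000 generated pairs; the
mixture finite-difference oracle on 200 random states (counts chosen to
exercise the parameter space while keeping the suite fast).

## Numerical choices

* Finite differences: central scheme throughout; default relative step
  10⁻⁶ for composition derivatives (balancing truncation against
  cancellation at double precision), 10⁻³ K for temperature derivatives,
  10⁻⁷·V for volume derivatives.
* Degenerate inputs: σ = 0 or b = 0 species are valid (zero cavity work);
  a missing attraction parameter zero-fills the attraction channel with a
  logged warning rather than failing; ρ₁b₁ ≥ 1 raises
  `OverpackedLiquidError` naming the offending product (and, in
  temperature scans, the offending temperature).
* Rounded-value comparisons carry an absolute guard of 10⁻⁹ against
  binary representation of decimal deltas.
* μ₁ is obtained from μ₂ by label exchange (the expression is symmetric
  under 1↔2), avoiding a second derivation.
* The Gibbs–Duhem check is performed in its fixed-(T,V) form,
  Σ Nᵢ·(∂μᵢ/∂N₂) = V·(∂P/∂N₂): when composition varies at fixed volume
  the pressure is not constant, so the familiar Σ Nᵢ·dμᵢ = 0 (fixed T, P)
  does not apply.

## Limitations

* Qualitative model by construction: cavity work is underestimated
  (free-volume treatment), so ΔS_x magnitudes are too small relative to
  scaled particle theory; do not use the numbers as quantitative
  predictions of solvation data.
* No attraction parameters are shipped for real liquids; the attraction
  channel is exercised with user-supplied or synthetic values only.
* Monoatomic-species assumption: treating n-alkanes, ethanol or benzene
  as spheres is a rough approximation, inherited from the reference
  dataset.
* P is metadata; isobaric derivatives are realised through α_P alone.
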