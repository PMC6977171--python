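# Methods

## Model and assumptions

The package implements the segment-based conductor-reference model of
liquid-phase solvation. Its assumptions, in the order they enter:

1. **Conductor reference.** Every molecule is characterized once by its
   σ-profile — surface area binned by induced screening charge density —
   computed upstream by quantum chemistry. The package consumes
   already-binned profiles; σ-averaging of raw cavity segments and any
   quantum-chemical step are out of scope.
2. **Pairwise surface contacts, no 3-D geometry.** The liquid is an
   ensemble of independent segment–segment contacts of effective area
   `a_eff`. Van der Waals energy is absorbed into the reference state and
   contributes exactly zero to all energy differences. Misfit energy is
   `a_eff·c_misfit·(σ+σ′)²`; the hydrogen-bond term uses the
   donor/acceptor form `a_eff·c_hb·min(0, min(0, σ_d+σ_HB)·max(0, σ_a−σ_HB))`
   with σ_d = min(σ,σ′), σ_a = max(σ,σ′). The widely printed compact form
   `c_hb·min(0, σσ′ + σ_HB²)` is selectable (`hb_form="product_threshold"`)
   for sensitivity analysis; the donor/acceptor form is the default
   because it reproduces the defining threshold behaviour exactly: the
   term vanishes on the whole square |σ|, |σ′| ≤ σ_HB.
3. **Mixtures.** A multicomponent solvent's profile is the
   mole-fraction-weighted sum of component profiles. Each component of a
   DES — salt, donor, water — is an independent mole-bearing species
   (1:0.9:0.6 ⇒ 2.5 mol of particles per formula set); salts such as
   choline chloride are treated as single unionised species with one
   profile. The pseudo-molecule convention (one mole per formula set) is
   available in the unit-conversion layer (`mole_basis="ratio"`) but is
   not used by the thermodynamics.
4. **Self-consistent σ-potential.** μ_S(σ) solves the fixed-point
   equation by successive substitution from μ ≡ 0. μ is stored per unit
   area so the solute chemical potential is a plain area-weighted sum
   over the solute profile — this keeps the potential equation and the
   chemical-potential quadrature dimensionally consistent without
   `a_eff` appearing twice. Quadrature over σ′ is the discrete bin sum;
   no sub-bin interpolation.
5. **Solubility.** `ln x = (μ_pure − μ_solution − ΔG_fus)/RT`, capped at
   x = 1 with a miscibility flag. The dilute mode evaluates the solute at
   infinite dilution; the iterative mode re-solves the solvent potential
   with the dissolved solute included at its current mole fraction until
   `|Δ ln x| < tol` (interpreted as concentration self-consistency; the
   solid phase is assumed pure throughout). Relative solubility
   log₁₀(x_a/x_b) is computed in dilute mode, where μ_pure and ΔG_fus
   cancel exactly — bit-identically in the implementation.
6. **Combinatorial term.** Default `none`: for ranking chemically similar
   media the size/shape correction largely cancels in relative
   solubilities. The `area_volume` option evaluates the
   Staverman–Guggenheim infinite-dilution expression
   `RT·[ln r + 1 − r − (z/2)·q·(ln(r/q) + 1 − r/q)]` with r and q the
   solute/solvent cavity volume and area ratios and z = 10.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `temperature` | 298.15 | K | room temperature of the shake-flask data |
| `a_eff` | 7.5 | Å² | effective segment contact area (also the contact area of the pair energies — the model does not distinguish them) |
| `c_misfit` | 4593.117… | kJ·mol⁻¹·Å⁻²·(e/Å²)⁻² | misfit coefficient |
| `c_hb` | 47742.229… | kJ·mol⁻¹·Å⁻²·(e/Å²)⁻² | hydrogen-bond coefficient |
| `sigma_hb` | 0.0082 | e/Å² | donor/acceptor polarity threshold |

`c_misfit` and `c_hb` are the open COSMO-SAC constants (Lin & Sandler
2002; α′ = 16466.72 and c_hb = 85580 kcal·Å⁴·mol⁻¹·e⁻² at a_eff =
7.5 Å²) converted to the package's per-area kJ units
(`c_misfit = α′/(2·a_eff)`, `c_hb = c_hb,SAC/a_eff`); the threshold keeps
the conventional ±0.0082 e/Å² value rather than COSMO-SAC's 0.0084. All
constants live in a versioned flat parameter file
(`descosmo/data/params_default.txt`) that `load_params`/`save_params`
round-trip bit-exactly; every computation accepts an explicit parameter
set, so nothing in the library is tied to the defaults.

The σ-grid defaults to −0.030 … +0.030 e/Å² in 0.001 steps (61 bins,
symmetric, containing σ = 0 exactly) and is configurable.

## Numerics

* The fixed-point map is evaluated with log-sum-exp; exponents reach
  ±50 at the grid extremes and would overflow naively.
* Successive substitution starts at μ ≡ 0. The hydrogen-bond term can
  make the undamped map 2-cycle on donor/acceptor-rich profiles, so an
  oscillation guard raises the damping to ≥ 0.5 as soon as the dominant
  update component alternates sign; an explicit base damping in [0, 1)
  may also be given. Defaults: `tol = 1e−8 kJ·mol⁻¹·Å⁻²`,
  `max_iter = 2000` (each sweep is one dense 61×61 pass; the budget
  covers slowly contracting smooth modes). Non-convergence is returned
  as a flagged result with residual diagnostics, never silently.
* Off-grid σ values in profile files are apportioned linearly to the two
  bracketing bins (conserves area and first moment); values within float
  round-off of a grid point are snapped to it so write→read is the
  identity.
* Ties in solvent rankings break lexicographically by solvent name.
* Degenerate inputs (zero-area profiles, zero denominators, below-LOQ
  operands in fold ratios) raise typed exceptions rather than producing
  NaNs.

## Synthetic data: what it emulates and what it does not

`synthetic_study` emulates the design of a screening campaign: solutes
and two-component solvent mixtures drawn from a peak library of Gaussian
σ-peaks (a neutral backbone plus donor/acceptor wings at ±0.014 and
±0.006 e/Å², i.e. on both sides of the ±0.0082 threshold), molar masses
150–550 g/mol for solutes, a true solubility table computed by the
package's own engine, and an "experimental" mg/g table obtained by
multiplying the true mole-fraction solubility by 10^ε with
ε ~ N(0, noise_sd²). Defaults are an 11-solute × 10-solvent layout and
noise_sd = 0.5 log₁₀ units, the scatter scale typical of
prediction-vs-experiment comparisons. Each solute's fusion energy is
drawn 5–30 kJ/mol above its best solvation advantage, so every cell is a
genuinely under-saturated solid — conversions never leave their valid
range and no cell saturates at the miscibility cap. All randomness
derives from one seed via independent substreams; identical seeds give
bitwise-identical studies.

What passing the closure tests shows: the pipeline profiles →
σ-potential → chemical potentials → solubility → unit conversion →
comparison statistics is exactly self-consistent (noise-free data
reproduce the identity fit to machine precision), and the statistics
degrade monotonically with measurement noise. What it does not show:
accuracy against laboratory data, which depends on the realism of the
σ-profiles and the interaction constants. Real profiles have
conformer-dependent fine structure, correlated donor/acceptor areas and
element-specific hydrogen-bond strengths that Gaussian peaks with one
global `c_hb` do not capture; absolute-solubility parity with
proprietary parameterizations is explicitly out of scope.

## Design choices that were genuinely open

* **Regression direction** in the comparison statistics: experimental
  log-solubility is regressed on predicted (the identity line is the
  reference; statistics are invariant to common log-scale shifts).
* **Below-LOQ cells** are excluded from every fit with a logged count,
  never imputed; APIs unquantifiable in the reference solvent get a
  per-API fallback reference (ethanol in the packaged study).
* **Fold-ratio rounding** follows the quoting convention one decimal
  below 10-fold, nearest integer above (`rounding="auto"`), with the
  explicit conventions also available.
* **Iterative mode semantics**: the self-consistency loop iterates the
  solute concentration in the liquid phase. An alternative reading —
  solid-phase activity iteration — would require solid-state inputs the
  model does not have.
* **Glucose DESs** are encoded as anhydrous glucose plus explicit water
  at the stated molar ratios (the monohydrate's water belongs to the
  water ratio); measured rather than nominal water content can be used
  by overriding the composition.

## Problem sizes

The test suite and acceptance script use 61-bin grids throughout;
closure runs use 8 solutes × 6 solvents and the noise study 20 seeds per
noise level, sizes at which the whole analysis completes in seconds
while exercising every pipeline stage.

## Known limitations

* Single conformer, single profile per species; no temperature-dependent
  hydrogen-bond scaling, no dispersion term, one global `c_hb`.
* Salts are neutral ion-pair pseudo-species; electrolyte physics
  (dissociation, long-range screening) is absent.
* ΔG_fus must be supplied for absolute solubilities of solids; only the
  relative mode is fusion-free.
* The fixed ±band drawn as a confidence interval in comparison plots is
  a visual aid with configurable width, not an inferential interval.
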