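# descosmo

σ-profile segment thermodynamics for solvent screening: predict and
rank-order the relative solubility of drug-like solutes in
multicomponent solvents — deep eutectic solvents (DES) in particular —
and confront the predictions with shake-flask measurements.

## Who this is for

Formulation scientists screening solvents for a poorly soluble active
pharmaceutical ingredient (API) face a combinatorial space: a DES is any
hydrogen-bond-acceptor/donor pair (choline chloride–urea, lactic
acid–glucose–water, …) that is liquid far below its components' melting
points, and millions of such combinations are plausible. This package
implements the statistical-thermodynamic machinery needed to rank those
solvents computationally before any wet-lab work, plus the bookkeeping
(unit conversions, fold ratios, rank statistics) to evaluate the ranking
against experimental solubility tables.

## The model

Each molecule is represented by its **σ-profile** p(σ): a histogram of
its cavity surface area (Å²) by the screening charge density σ (e/Å²)
that a perfect conductor would induce on that surface. Two surface
segments of polarity σ, σ′ in contact over an effective area a_eff pick
up, relative to the conductor reference,

* a **misfit** penalty  E_mf = a_eff·c_misfit·(σ + σ′)²  (zero for a
  perfect electrostatic fit σ′ = −σ), and
* a **hydrogen-bond** gain
  E_hb = a_eff·c_hb·min(0, min(0, σ_don + σ_HB)·max(0, σ_acc − σ_HB)),
  available only when a donor segment (σ < −σ_HB) meets an acceptor
  segment (σ > +σ_HB); σ_HB = 0.0082 e/Å².

A (mixture) solvent's profile is the mole-fraction-weighted sum of its
components' profiles; every DES constituent, water included, counts as a
mole-bearing component. The solvent's **σ-potential** μ_S(σ) — its
affinity for a segment of polarity σ — solves the fixed point

    μ_S(σ) = −(RT/a_eff) · ln Σ_σ′ p_S(σ′) · exp[(a_eff·μ_S(σ′) − E(σ,σ′))/RT]

and the solute's pseudo-chemical potential is the area-weighted sum
μ_S^X = γ_comb + Σ_σ p^X(σ)·μ_S(σ). Mole-fraction solubility of a solid
follows from

    ln x_S = (μ^X_pure − μ_S^X − ΔG_fus) / RT ,

and the **relative** solubility between two solvents,
log₁₀(x_a/x_b) = (μ^X_Sb − μ^X_Sa)/(RT·ln 10), needs neither the
pure-liquid term nor the fusion energy ΔG_fus — which is why relative
ranking is the robust screening quantity.

## Worked example

```python
import descosmo as d

grid = d.SigmaGrid()                  # −0.030 … +0.030 e/Å², 61 bins
params = d.default_params()           # shipped interaction constants

# a water-like solvent, an aprotic ester-like solvent, an amphoteric drug
water = d.Species("water", 18.015, d.make_gaussian_profile(
    grid, [(0.0, 0.004, 25.0), (-0.015, 0.0025, 9.0), (0.015, 0.0025, 9.0)]))
ester = d.Species("ester", 88.1, d.make_gaussian_profile(
    grid, [(0.0, 0.004, 90.0), (0.010, 0.003, 20.0)]))
drug = d.Species("drug", 230.3, d.make_gaussian_profile(
    grid, [(0.0, 0.005, 180.0), (-0.013, 0.003, 35.0), (0.012, 0.003, 30.0)]))

des = d.SolventMixture.from_ratios([(water, 0.6), (ester, 1.0)],
                                   label="ester:water=1:0.6")
rec = d.relative_log10_solubility(drug, des, d.SolventMixture.pure(water), params)
print(f"log10(x_DES / x_water) = {rec.log10_relative:+.2f}")

ranking = d.rank_solvents(
    drug,
    [d.SolventMixture.pure(water), d.SolventMixture.pure(ester, label="ester"), des],
    params)
for name, rel in ranking:
    print(f"{name:>20s}  {rel:+.2f}")
```

prints

```
log10(x_DES / x_water) = +3.53
               ester  +5.59
   ester:water=1:0.6  +3.53
               water  +0.00
```

The mostly apolar drug is predicted 3.5 log units (mole/mole) more
soluble in the ester–water mixture than in water, and the pure ester
ranks best; the last column is log₁₀ solubility relative to the first
listed solvent.

The packaged study fixtures (`descosmo.load_fixtures()`) carry the
measured solubilities of 11 APIs in six DESs, water, ethanol, glycerol
and PEG 300, and `descosmo.composition` provides the mg/g ↔ mole-fraction
conversions and fold/log-unit arithmetic used to summarize them. A
`descosmo` CLI exposes the pipeline stages (`profile-validate`,
`sigma-potential`, `predict`, `rank`, `compare`, `simulate`,
`run-study`, `fixture-summary`).

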