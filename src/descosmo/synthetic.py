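"""Synthetic σ-profiles, solvent sets and noisy solubility tables.

Quantum-chemistry σ-profiles are expensive to produce; this module
generates physically structured stand-ins so the whole pipeline —
profiles → σ-potentials → chemical potentials → (relative) solubility →
comparison statistics — can be exercised and validated end to end.

A synthetic species is a sum of Gaussian peaks on the σ-axis: a broad
neutral peak near σ = 0 plus optional donor (σ < −σ_HB) and acceptor
(σ > +σ_HB) peaks, mirroring the three-band structure of real profiles.
A synthetic study draws a set of solid solutes and two-component liquid
solvent mixtures, computes the *true* solubility table with the package's
own engine, and then perturbs it with multiplicative lognormal
measurement noise (additive Gaussian on the log10 scale) to produce an
"experimental" mg/g table of the same shape as a screening campaign.

Every solute's fusion penalty is drawn so that it remains an
under-saturated solid in all study solvents (solid-limited solubility);
the generator therefore never produces fully miscible cells, and the
mg/g ↔ mole-fraction conversions stay in their valid range.

All randomness derives from the single seed in :class:`SyntheticSpec`;
identical seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .composition import CompositionSpec, SolubilityRecord, mole_fraction_to_mg_per_g
from .exceptions import ValidationError
from .interactions import InteractionParams, build_interaction_matrix
from .potential import solve_sigma_potential
from .profiles import SigmaGrid, SigmaProfile, SolventMixture, Species, mix_profiles
from .solubility import LN10, pure_chemical_potential, solute_chemical_potential

__all__ = ["SyntheticSpec", "SyntheticStudy", "make_gaussian_profile", "synthetic_study"]

#: (center e/Å², width e/Å², area Å²) peak templates: a neutral backbone,
#: strong/weak hydrogen-bond donor wings (negative σ) and acceptor wings.
DEFAULT_PEAK_LIBRARY = (
    (0.000, 0.0045, 220.0),   # neutral backbone
    (-0.014, 0.0030, 55.0),   # strong donor
    (0.014, 0.0030, 55.0),    # strong acceptor
    (-0.006, 0.0030, 70.0),   # weakly polar negative
    (0.006, 0.0030, 70.0),    # weakly polar positive
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic screening study.

    ``noise_sd`` is the standard deviation of the multiplicative lognormal
    measurement noise on solubility, expressed in log10 units (0.5 spans
    the ~1 log-unit scatter typical of prediction-vs-experiment
    comparisons).  ``n_solutes``/``n_solvents`` default to the 11 × 10
    layout of a full screening campaign.
    """

    seed: int
    n_solutes: int = 11
    n_solvents: int = 10
    peak_library: tuple[tuple[float, float, float], ...] = DEFAULT_PEAK_LIBRARY
    noise_sd: float = 0.5
    gibbs_fusion_range: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_solutes < 1 or self.n_solvents < 2:
            raise ValidationError("need ≥ 1 solute and ≥ 2 solvents")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        lo, hi = self.gibbs_fusion_range
        if not 0 <= lo <= hi:
            raise ValidationError("gibbs_fusion_range must be 0 ≤ lo ≤ hi")
        for center, width, area in self.peak_library:
            if width <= 0 or area <= 0:
                raise ValidationError("peak widths and areas must be > 0")


def make_gaussian_profile(
    grid: SigmaGrid, peaks: list[tuple[float, float, float]]
) -> SigmaProfile:
    """Sum of discretized Gaussian peaks, each renormalized to its area.

    Each (center, width, area) peak is evaluated at the bin centres and
    scaled so its binned mass equals ``area`` exactly; total profile area
    is therefore Σ areas regardless of discretization or truncation.
    """
    sig = grid.values
    total = np.zeros(grid.n_bins)
    for center, width, area in peaks:
        if not grid.sigma_min <= center <= grid.sigma_max:
            raise ValidationError(
                f"peak center {center:g} outside grid "
                f"[{grid.sigma_min:g}, {grid.sigma_max:g}]"
            )
        if width <= 0 or area <= 0:
            raise ValidationError("peak width and area must be > 0")
        shape = np.exp(-0.5 * ((sig - center) / width) ** 2)
        total += area * shape / shape.sum()
    return SigmaProfile(grid, total)


@dataclass
class SyntheticStudy:
    """Output bundle of :func:`synthetic_study`."""

    spec: SyntheticSpec
    solutes: list[Species]
    solvents: list[SolventMixture]
    solvent_specs: list[CompositionSpec]
    #: (solute, solvent) → true log10 mole-fraction solubility
    true_log10_x: dict[tuple[str, str], float]
    #: (solute, solvent) → true log10 solubility relative to the first solvent
    true_log10_relative: dict[tuple[str, str], float]
    #: noisy "experimental" measurements, mg API per g solvent
    experimental_records: list[SolubilityRecord]
    solute_molar_masses: dict[str, float]

    @property
    def reference_solvent(self) -> str:
        return self.solvents[0].display_name

    def experimental_log10_x(self) -> dict[tuple[str, str], float]:
        """Experimental table converted back to log10 mole fraction."""
        from .composition import mg_per_g_to_mole_fraction

        specs = {s.label: s for s in self.solvent_specs}
        out = {}
        for rec in self.experimental_records:
            if rec.mean is None:
                continue
            x = mg_per_g_to_mole_fraction(
                rec.mean,
                self.solute_molar_masses[rec.api_name],
                specs[rec.solvent_label],
            )
            out[(rec.api_name, rec.solvent_label)] = math.log10(x)
        return out


def _random_peaks(
    rng: np.random.Generator,
    library: tuple[tuple[float, float, float], ...],
    grid: SigmaGrid,
) -> list[tuple[float, float, float]]:
    """Draw a species as a jittered, rescaled subset of the peak library."""
    peaks = []
    for i, (center, width, area) in enumerate(library):
        keep = i == 0 or rng.random() < 0.7  # backbone always present
        jitter = rng.uniform(-0.002, 0.002)
        scale = rng.uniform(0.4, 1.6)
        if keep:
            c = float(np.clip(center + jitter, grid.sigma_min, grid.sigma_max))
            peaks.append((c, width, area * scale))
    return peaks


def synthetic_study(
    spec: SyntheticSpec, params: InteractionParams, grid: SigmaGrid | None = None
) -> SyntheticStudy:
    """Generate a full synthetic screening study.

    Solutes and solvent components are drawn from the peak library;
    solvents are two-component mixtures (the first doubles as the
    reference solvent of the relative table).  The true table comes from
    the dilute solubility engine; the experimental table multiplies the
    true mole-fraction solubility by 10^ε, ε ~ N(0, noise_sd²), and
    converts to mg/g.
    """
    grid = grid or SigmaGrid()
    root = np.random.SeedSequence(spec.seed)
    ss_solv, ss_solute, ss_noise = root.spawn(3)
    rng_solv = np.random.default_rng(ss_solv)
    rng_solute = np.random.default_rng(ss_solute)
    rng_noise = np.random.default_rng(ss_noise)

    matrix = build_interaction_matrix(grid, params)

    solvents: list[SolventMixture] = []
    solvent_specs: list[CompositionSpec] = []
    for j in range(spec.n_solvents):
        label = f"S{j:02d}"
        comps = []
        ratios = []
        for part in ("a", "b"):
            prof = make_gaussian_profile(
                grid, _random_peaks(rng_solv, spec.peak_library, grid)
            )
            mass = float(rng_solv.uniform(18.0, 150.0))
            comps.append(Species(name=f"{label}{part}", molar_mass=mass, profile=prof))
            ratios.append(float(rng_solv.uniform(0.5, 2.0)))
        solvents.append(
            SolventMixture.from_ratios(list(zip(comps, ratios)), label=label)
        )
        solvent_specs.append(
            CompositionSpec(
                label,
                tuple((sp.name, sp.molar_mass, r) for sp, r in zip(comps, ratios)),
                role="des",
            )
        )

    # solvent σ-potentials, solved once each
    potentials = {
        sv.display_name: solve_sigma_potential(
            mix_profiles(sv), params, matrix=matrix
        )
        for sv in solvents
    }

    rt = params.rt
    solutes: list[Species] = []
    masses: dict[str, float] = {}
    true_log10_x: dict[tuple[str, str], float] = {}
    true_rel: dict[tuple[str, str], float] = {}
    records: list[SolubilityRecord] = []
    ref_label = solvents[0].display_name
    for i in range(spec.n_solutes):
        name = f"API{i:02d}"
        prof = make_gaussian_profile(
            grid, _random_peaks(rng_solute, spec.peak_library, grid)
        )
        mass = float(rng_solute.uniform(150.0, 550.0))
        draw = float(rng_solute.uniform(*spec.gibbs_fusion_range))
        sp = Species(name=name, molar_mass=mass, profile=prof)
        mu_pure = pure_chemical_potential(sp, params, matrix=matrix)
        mu_in = {
            sv.display_name: solute_chemical_potential(
                sp, potentials[sv.display_name], sv, params
            )
            for sv in solvents
        }
        # crystalline solid under-saturated in every study solvent: the
        # fusion penalty exceeds the best solvation advantage by the draw
        dg = max(0.0, max(mu_pure - mu for mu in mu_in.values())) + draw
        sp.gibbs_fusion = dg
        solutes.append(sp)
        masses[name] = mass

        for sv in solvents:
            lbl = sv.display_name
            ln_x = (mu_pure - mu_in[lbl] - dg) / rt
            log10_x = ln_x / LN10
            true_log10_x[(name, lbl)] = log10_x
            true_rel[(name, lbl)] = (mu_in[ref_label] - mu_in[lbl]) / (rt * LN10)
            eps = float(rng_noise.normal(0.0, spec.noise_sd)) if spec.noise_sd else 0.0
            x_noisy = min(10.0 ** (log10_x + eps), 0.99)
            mg_g = mole_fraction_to_mg_per_g(
                x_noisy, mass, solvent_specs[solvents.index(sv)]
            )
            records.append(
                SolubilityRecord(api_name=name, solvent_label=lbl, mean=mg_g, sd=0.0)
            )

    return SyntheticStudy(
        spec=spec,
        solutes=solutes,
        solvents=solvents,
        solvent_specs=solvent_specs,
        true_log10_x=true_log10_x,
        true_log10_relative=true_rel,
        experimental_records=records,
        solute_molar_masses=masses,
    )
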