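"""Chemical potentials and solid–liquid equilibrium solubility.

With the solvent's σ-potential in hand, the pseudo-chemical potential of a
solute X in solvent S is the area-weighted sum over the solute profile

    μ_S^X = γ_comb + Σ_k p^X(σ_k) · μ_S(σ_k)

(p^X in Å² per bin, μ per Å², result kJ/mol).  The combinatorial term
γ_comb corrects for size/shape differences between solute and solvent; by
default it is zero, and an area/volume Staverman–Guggenheim-style form is
available for sensitivity analysis (see :func:`combinatorial_term`).

The mole-fraction solubility of a solid then follows from

    ln x_S = (μ^X_pure − μ_S^X − ΔG_fus) / (R·T)

capped at ln x = 0 (full miscibility).  ΔG_fus is the free energy of
fusion — a pure solid-state property that is hard to obtain ab initio.
The package therefore also computes *relative* solubility between two
solvents, log10(x_a/x_b), in which both μ^X_pure and ΔG_fus cancel
exactly and are never required; this is the quantity best suited to
solvent ranking.

Two solubility modes are provided: ``dilute`` evaluates the solute at
infinite dilution in the unperturbed solvent, and ``iterative``
self-consistently re-solves the solvent σ-potential with the solute
included at its current predicted mole fraction until the composition
stops changing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


from .exceptions import ConvergenceError, GridMismatchError, ValidationError
from .interactions import InteractionMatrix, InteractionParams, build_interaction_matrix
from .potential import SigmaPotential, solve_sigma_potential
from .profiles import SolventMixture, Species, mix_profiles

__all__ = [
    "PredictionRecord",
    "combinatorial_term",
    "solute_chemical_potential",
    "pure_chemical_potential",
    "ln_solubility_dilute",
    "ln_solubility_iterative",
    "relative_log10_solubility",
    "rank_solvents",
]

LN10 = math.log(10.0)


@dataclass
class PredictionRecord:
    """One solute-in-solvent prediction.

    ``ln_x`` is the natural-log mole-fraction solubility (≤ 0, capped);
    ``log10_relative`` is log10(x_solvent / x_reference) and is present
    iff a reference solvent is.  ``used_gibbs_fusion`` records the ΔG_fus
    that entered the calculation, or the string ``"cancelled"`` for
    relative predictions where it drops out.
    """

    solute_name: str
    solvent_name: str
    ln_x: float | None = None
    reference_solvent_name: str | None = None
    log10_relative: float | None = None
    temperature: float = 298.15
    used_gibbs_fusion: float | str | None = None
    miscible: bool = False
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        if self.ln_x is not None and self.ln_x > 0:
            raise ValidationError("ln_x must be ≤ 0 (mole fraction ≤ 1)")
        if (self.log10_relative is None) != (self.reference_solvent_name is None):
            raise ValidationError(
                "log10_relative and reference_solvent_name must be present together"
            )


def combinatorial_term(
    solute: Species, solvent: SolventMixture, params: InteractionParams
) -> float:
    """Size/shape correction γ_comb, kJ/mol, at infinite dilution.

    ``combinatorial_form="none"`` returns 0.  ``"area_volume"`` evaluates
    the Staverman–Guggenheim infinite-dilution term from the solute/solvent
    cavity area and volume ratios r = V_X/V̄_S and q = A_X/Ā_S:

        γ_comb = R·T·[ ln r + 1 − r − (z/2)·q·( ln(r/q) + 1 − r/q ) ]

    with coordination number z (default 10).
    """
    if params.combinatorial_form == "none":
        return 0.0
    a_bar = solvent.mean_cosmo_area()
    v_bar = solvent.mean_cosmo_volume()
    if v_bar is None or solute.cosmo_volume is None:
        raise ValidationError(
            "area_volume combinatorial form needs cosmo_volume on all species"
        )
    r = solute.cosmo_volume / v_bar
    q = solute.cosmo_area / a_bar
    if r <= 0 or q <= 0:
        raise ValidationError("cavity area/volume ratios must be positive")
    z2 = params.combinatorial_z / 2.0
    ln_gamma = math.log(r) + 1.0 - r - z2 * q * (math.log(r / q) + 1.0 - r / q)
    return params.rt * ln_gamma


def solute_chemical_potential(
    solute: Species,
    potential: SigmaPotential,
    solvent: SolventMixture,
    params: InteractionParams,
) -> float:
    """μ_S^X in kJ/mol: combinatorial term plus profile-weighted σ-potential."""
    if solute.profile.grid != potential.grid:
        raise GridMismatchError("solute profile and σ-potential are on different grids")
    residual_part = float(solute.profile.area_per_bin @ potential.mu)
    return combinatorial_term(solute, solvent, params) + residual_part


def pure_chemical_potential(
    species: Species,
    params: InteractionParams,
    *,
    matrix: InteractionMatrix | None = None,
) -> float:
    """μ^X of the pure liquid: the species solvated in itself."""
    pot = solve_sigma_potential(species.profile, params, matrix=matrix)
    if not pot.converged:
        raise ConvergenceError(
            f"σ-potential for pure {species.name!r} did not converge "
            f"(residual {pot.residual:.3g})"
        )
    return solute_chemical_potential(species, pot, SolventMixture.pure(species), params)


def _resolve_gibbs_fusion(solute: Species, gibbs_fusion: float | None) -> float:
    value = gibbs_fusion if gibbs_fusion is not None else solute.gibbs_fusion
    if value is None:
        raise ValidationError(
            f"{solute.name}: ΔG_fus is required for absolute solubility of a solid "
            "— pass gibbs_fusion (0 for a liquid solute) or use relative mode, "
            "where it cancels"
        )
    if value < 0:
        raise ValidationError("ΔG_fus must be ≥ 0")
    return float(value)


def ln_solubility_dilute(
    solute: Species,
    solvent: SolventMixture,
    params: InteractionParams,
    gibbs_fusion: float | None = None,
    *,
    matrix: InteractionMatrix | None = None,
) -> PredictionRecord:
    """Infinite-dilution mole-fraction solubility, ln x (capped at 0)."""
    dg = _resolve_gibbs_fusion(solute, gibbs_fusion)
    if matrix is None:
        matrix = build_interaction_matrix(solute.profile.grid, params)
    pot = solve_sigma_potential(mix_profiles(solvent), params, matrix=matrix)
    mu_solution = solute_chemical_potential(solute, pot, solvent, params)
    mu_pure = pure_chemical_potential(solute, params, matrix=matrix)
    ln_x = (mu_pure - mu_solution - dg) / params.rt
    miscible = ln_x >= 0.0
    return PredictionRecord(
        solute_name=solute.name,
        solvent_name=solvent.display_name,
        ln_x=min(ln_x, 0.0),
        temperature=params.temperature,
        used_gibbs_fusion=dg,
        miscible=miscible,
        converged=pot.converged,
        iterations=pot.iterations,
    )


def _mixture_with_solute(
    solvent: SolventMixture, solute: Species, x: float
) -> SolventMixture:
    """Solvent scaled to (1−x) with the solute merged in at mole fraction x."""
    parts: dict[str, tuple[Species, float]] = {}
    for sp, frac in solvent.components:
        parts[sp.name] = (sp, frac * (1.0 - x))
    if solute.name in parts:
        sp, frac = parts[solute.name]
        parts[solute.name] = (sp, frac + x)
    else:
        parts[solute.name] = (solute, x)
    return SolventMixture(list(parts.values()), label=solvent.display_name)


def ln_solubility_iterative(
    solute: Species,
    solvent: SolventMixture,
    params: InteractionParams,
    gibbs_fusion: float | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    matrix: InteractionMatrix | None = None,
) -> PredictionRecord:
    """Self-consistent solubility: the dissolved solute is part of the solvent.

    Starting from the dilute estimate x₀, each sweep rebuilds the liquid as
    solvent·(1−x_t) + solute·x_t, re-solves the σ-potential, and re-applies
    the solubility equation.  Converges when |ln x_{t+1} − ln x_t| < tol;
    a persistent oscillation is reported via ``converged=False``.
    """
    dg = _resolve_gibbs_fusion(solute, gibbs_fusion)
    if matrix is None:
        matrix = build_interaction_matrix(solute.profile.grid, params)
    mu_pure = pure_chemical_potential(solute, params, matrix=matrix)

    dilute = ln_solubility_dilute(solute, solvent, params, dg, matrix=matrix)
    ln_x = dilute.ln_x
    converged = False
    it = 0
    prev_delta = None
    for it in range(1, max_iter + 1):
        x = min(1.0, math.exp(ln_x))
        if x >= 1.0:
            ln_x_new = 0.0
        else:
            liquid = _mixture_with_solute(solvent, solute, x)
            pot = solve_sigma_potential(
                mix_profiles(liquid), params, matrix=matrix
            )
            mu_solution = solute_chemical_potential(solute, pot, liquid, params)
            ln_x_new = min(0.0, (mu_pure - mu_solution - dg) / params.rt)
        delta = ln_x_new - ln_x
        if abs(delta) < tol:
            ln_x = ln_x_new
            converged = True
            break
        if prev_delta is not None and delta * prev_delta < 0:
            ln_x_new = 0.5 * (ln_x + ln_x_new)  # damp oscillation
            delta = ln_x_new - ln_x
        prev_delta = delta
        ln_x = ln_x_new
    return PredictionRecord(
        solute_name=solute.name,
        solvent_name=solvent.display_name,
        ln_x=ln_x,
        temperature=params.temperature,
        used_gibbs_fusion=dg,
        miscible=ln_x >= 0.0,
        converged=converged,
        iterations=it,
    )


def relative_log10_solubility(
    solute: Species,
    solvent_a: SolventMixture,
    solvent_b: SolventMixture,
    params: InteractionParams,
    *,
    matrix: InteractionMatrix | None = None,
) -> PredictionRecord:
    """log10(x_a / x_b) at infinite dilution.

    Both the pure-liquid chemical potential and ΔG_fus cancel exactly in
    the ratio, so no fusion data is needed — the key advantage of ranking
    solvents by relative rather than absolute solubility.
    """
    if matrix is None:
        matrix = build_interaction_matrix(solute.profile.grid, params)
    mus = []
    for solvent in (solvent_a, solvent_b):
        pot = solve_sigma_potential(mix_profiles(solvent), params, matrix=matrix)
        mus.append(solute_chemical_potential(solute, pot, solvent, params))
    log10_rel = (mus[1] - mus[0]) / (params.rt * LN10)
    return PredictionRecord(
        solute_name=solute.name,
        solvent_name=solvent_a.display_name,
        reference_solvent_name=solvent_b.display_name,
        log10_relative=log10_rel,
        temperature=params.temperature,
        used_gibbs_fusion="cancelled",
    )


def rank_solvents(
    solute: Species,
    solvents: list[SolventMixture],
    params: InteractionParams,
    *,
    matrix: InteractionMatrix | None = None,
) -> list[tuple[str, float]]:
    """Rank solvents for a solute, best first.

    Returns (solvent_name, log10 relative solubility vs. the first listed
    solvent), sorted descending; exact ties break lexicographically by
    name.  The ranking is invariant to the choice of reference solvent
    (it only shifts all log-ratios by a constant).
    """
    if len(solvents) < 2:
        raise ValidationError("ranking needs at least two solvents")
    if matrix is None:
        matrix = build_interaction_matrix(solute.profile.grid, params)
    mus = {}
    for solvent in solvents:
        pot = solve_sigma_potential(mix_profiles(solvent), params, matrix=matrix)
        mus[solvent.display_name] = solute_chemical_potential(
            solute, pot, solvent, params
        )
    ref_name = solvents[0].display_name
    rel = {
        name: (mus[ref_name] - mu) / (params.rt * LN10) for name, mu in mus.items()
    }
    return sorted(rel.items(), key=lambda kv: (-kv[1], kv[0]))
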