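"""Self-consistent σ-potential of a solvent.

The σ-potential μ_S(σ) is the reversible work (per unit contact area) of
inserting a surface segment of polarity σ into solvent S.  On a discrete
σ-grid with normalized profile weights w_l it is the fixed point of

    μ(σ_k) = −(RT / a_eff) · ln Σ_l w_l · exp[ (a_eff·μ(σ_l) − E(σ_k, σ_l)) / RT ]

where E is the per-contact interaction energy (misfit + hydrogen bond,
kJ/mol).  μ is stored per unit area (kJ·mol⁻¹·Å⁻²) so that the solute
chemical potential is a plain area-weighted sum over the solute profile.

The map is iterated by successive substitution starting from μ ≡ 0; for
physical parameters it is a contraction, and damping is switched on only
if the residual starts to oscillate (sign-alternating updates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import DegenerateInputError, ValidationError
from .interactions import InteractionMatrix, InteractionParams, build_interaction_matrix
from .profiles import SigmaGrid, SigmaProfile, normalize_profile

__all__ = ["SigmaPotential", "solve_sigma_potential"]


@dataclass
class SigmaPotential:
    """μ_S(σ) on a grid, kJ·mol⁻¹·Å⁻², with convergence diagnostics."""

    grid: SigmaGrid
    mu: np.ndarray
    temperature: float
    converged: bool
    iterations: int
    residual: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (self.grid.n_bins,):
            raise ValidationError("μ shape does not match grid")
        if not np.all(np.isfinite(self.mu)):
            raise ValidationError("non-finite σ-potential")


def _fixed_point_map(
    mu: np.ndarray, log_w: np.ndarray, energy: np.ndarray, a_eff: float, rt: float
) -> np.ndarray:
    # exponent[k, l] = (a_eff·μ_l − E_kl)/RT; log-sum-exp over l for stability
    expo = (a_eff * mu[None, :] - energy) / rt + log_w[None, :]
    return -(rt / a_eff) * logsumexp(expo, axis=1)


def solve_sigma_potential(
    profile: SigmaProfile,
    params: InteractionParams,
    *,
    matrix: InteractionMatrix | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    damping: float | None = None,
) -> SigmaPotential:
    """Solve the σ-potential fixed point for a (mixture) profile.

    Parameters
    ----------
    profile
        Solvent σ-profile (area-weighted); must have positive total area.
    params
        Interaction constants; sets temperature and the energy surface.
    matrix
        Optional precomputed interaction matrix on the profile's grid.
    tol
        Convergence threshold on the max-norm of the update,
        kJ·mol⁻¹·Å⁻².
    max_iter
        Iteration budget (each sweep is one dense n×n pass, so generous
        budgets are cheap); on exhaustion the result carries
        ``converged=False`` rather than raising.
    damping
        Base fraction of the previous iterate mixed into each update
        (default 0, i.e. plain successive substitution).  Independently of
        this base level, damping of at least 0.5 is switched on
        automatically if the update starts sign-alternating — the
        hydrogen-bond term can make the undamped map 2-cycle on
        donor/acceptor-rich profiles.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    if damping is not None and not (0.0 <= damping < 1.0):
        raise ValidationError("damping must lie in [0, 1)")
    w = normalize_profile(profile)  # raises DegenerateInputError on zero area
    active = w > 0
    if not np.any(active):
        raise DegenerateInputError("profile has no populated bins")
    log_w = np.full_like(w, -np.inf)
    log_w[active] = np.log(w[active])

    if matrix is None:
        matrix = build_interaction_matrix(profile.grid, params)
    energy = matrix.energy
    rt = params.rt
    a_eff = params.a_eff

    mu = np.zeros(profile.grid.n_bins)
    beta = 0.0 if damping is None else damping
    prev_update = None
    residual = np.inf
    for it in range(1, max_iter + 1):
        target = _fixed_point_map(mu, log_w, energy, a_eff, rt)
        update = target - mu
        residual = float(np.max(np.abs(update)))
        if residual < tol:
            return SigmaPotential(
                profile.grid, target, params.temperature, True, it, residual
            )
        if prev_update is not None:
            # oscillation guard: dominant component flips sign each sweep
            k = int(np.argmax(np.abs(update)))
            if update[k] * prev_update[k] < 0:
                beta = max(beta, 0.5)
        prev_update = update
        mu = beta * mu + (1.0 - beta) * target
    return SigmaPotential(profile.grid, mu, params.temperature, False, max_iter, residual)
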