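"""Pairwise segment interaction energies: misfit + hydrogen bond.

Two surface segments of charge density σ and σ′ brought into contact over
an effective area ``a_eff`` pick up two energy contributions relative to
the perfectly screened conductor reference state:

* **misfit** — an electrostatic penalty when the two screening charges do
  not cancel: ``E_mf = a_eff · c_misfit · (σ + σ′)²`` (always ≥ 0, zero
  for a perfect fit σ′ = −σ);
* **hydrogen bond** — an attraction available only when one segment is a
  sufficiently polar donor (σ < −σ_HB) and the other a sufficiently polar
  acceptor (σ > +σ_HB).  The default ``donor_acceptor`` functional form is

  ``E_hb = a_eff · c_hb · min(0, min(0, σ_don + σ_HB) · max(0, σ_acc − σ_HB))``

  with σ_don = min(σ, σ′), σ_acc = max(σ, σ′); it is ≤ 0 and identically
  zero unless both thresholds are overcome.  The alternative
  ``product_threshold`` form ``a_eff · c_hb · min(0, σ·σ′ + σ_HB²)`` is
  provided for sensitivity analysis.

The van der Waals contribution is absorbed into the reference state and is
identically zero here.  Total energy is the sum of the two terms.

Default coefficients are the open COSMO-SAC reparameterization constants
(Lin & Sandler 2002), converted to this package's per-area units; they are
shipped in a versioned parameter file and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import R_KJ_PER_MOL_K, ROOM_TEMPERATURE_K
from .exceptions import ValidationError
from .profiles import SigmaGrid

__all__ = [
    "InteractionParams",
    "InteractionMatrix",
    "misfit_energy",
    "hb_energy",
    "total_energy",
    "build_interaction_matrix",
    "load_params",
    "save_params",
    "default_params",
]

PARAMS_VERSION = "1"

# COSMO-SAC 2002 constants: alpha' = 16466.72 kcal·Å⁴·mol⁻¹·e⁻²,
# c_hb = 85580 kcal·Å⁴·mol⁻¹·e⁻², a_eff = 7.5 Å².  Converted:
# c_misfit = alpha'/(2·a_eff)·4.184, c_hb = c_hb/a_eff·4.184.
_A_EFF_DEFAULT = 7.5
_C_MISFIT_DEFAULT = 16466.72 * 4.184 / (2.0 * _A_EFF_DEFAULT)  # 4593.117...
_C_HB_DEFAULT = 85580.0 * 4.184 / _A_EFF_DEFAULT  # 47742.229...


@dataclass(frozen=True)
class InteractionParams:
    """All model constants in one serializable bundle.

    Units: temperature K; a_eff Å²; c_misfit and c_hb
    kJ·mol⁻¹·Å⁻²·(e/Å²)⁻²; sigma_hb e/Å².  ``a_eff`` plays the role of
    both the contact area in the pair energies and the effective segment
    area in the σ-potential — the model does not distinguish them.
    """

    temperature: float = ROOM_TEMPERATURE_K
    a_eff: float = _A_EFF_DEFAULT
    c_misfit: float = _C_MISFIT_DEFAULT
    c_hb: float = _C_HB_DEFAULT
    sigma_hb: float = 0.0082
    hb_form: str = "donor_acceptor"
    combinatorial_form: str = "none"
    combinatorial_z: float = 10.0  # SG coordination number, used by area_volume
    version: str = PARAMS_VERSION

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0 K")
        if self.a_eff <= 0:
            raise ValidationError("a_eff must be > 0")
        if self.c_misfit < 0 or self.c_hb < 0:
            raise ValidationError("c_misfit and c_hb must be ≥ 0")
        if self.sigma_hb <= 0:
            raise ValidationError("sigma_hb must be > 0")
        if self.hb_form not in ("donor_acceptor", "product_threshold"):
            raise ValidationError(f"unknown hb_form {self.hb_form!r}")
        if self.combinatorial_form not in ("none", "area_volume"):
            raise ValidationError(
                f"unknown combinatorial_form {self.combinatorial_form!r}"
            )

    @property
    def rt(self) -> float:
        """R·T in kJ/mol."""
        return R_KJ_PER_MOL_K * self.temperature

    def with_(self, **kwargs) -> "InteractionParams":
        return replace(self, **kwargs)


def misfit_energy(sigma, sigma_prime, params: InteractionParams):
    """Electrostatic misfit energy per contact, kJ/mol.  Vectorized."""
    s = np.asarray(sigma, dtype=float)
    sp = np.asarray(sigma_prime, dtype=float)
    out = params.a_eff * params.c_misfit * (s + sp) ** 2
    return out if out.ndim else float(out)


def hb_energy(sigma, sigma_prime, params: InteractionParams):
    """Hydrogen-bond energy per contact, kJ/mol (always ≤ 0).  Vectorized."""
    s = np.asarray(sigma, dtype=float)
    sp = np.asarray(sigma_prime, dtype=float)
    if params.hb_form == "donor_acceptor":
        s_don = np.minimum(s, sp)
        s_acc = np.maximum(s, sp)
        core = np.minimum(0.0, s_don + params.sigma_hb) * np.maximum(
            0.0, s_acc - params.sigma_hb
        )
        out = params.a_eff * params.c_hb * np.minimum(0.0, core)
    else:  # product_threshold
        out = params.a_eff * params.c_hb * np.minimum(0.0, s * sp + params.sigma_hb**2)
    return out if out.ndim else float(out)


def total_energy(sigma, sigma_prime, params: InteractionParams):
    """Misfit + hydrogen bond, kJ/mol per contact (vdW is zero by construction)."""
    out = np.asarray(misfit_energy(sigma, sigma_prime, params)) + np.asarray(
        hb_energy(sigma, sigma_prime, params)
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InteractionMatrix:
    """Precomputed contact energies over a σ-grid: energy[k, l] kJ/mol."""

    grid: SigmaGrid
    energy: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        if e.shape != (self.grid.n_bins, self.grid.n_bins):
            raise ValidationError("energy matrix shape does not match grid")
        object.__setattr__(self, "energy", e)


def build_interaction_matrix(
    grid: SigmaGrid, params: InteractionParams
) -> InteractionMatrix:
    """Tabulate total_energy(σ_k, σ_l) on the grid; exactly symmetric."""
    sig = grid.values
    # (σ+σ′)² and min/max are exactly symmetric in the arguments, so the
    # vectorized evaluation is bit-symmetric without post-processing.
    e = total_energy(sig[:, None], sig[None, :], params)
    return InteractionMatrix(grid, e)


# ---------------------------------------------------------------------------
# Parameter file I/O — flat "name value  # unit, provenance" text, bit-exact.

_PARAM_FIELDS = {
    "temperature": ("K", float),
    "a_eff": ("A^2", float),
    "c_misfit": ("kJ/mol/A^2/(e/A^2)^2", float),
    "c_hb": ("kJ/mol/A^2/(e/A^2)^2", float),
    "sigma_hb": ("e/A^2", float),
    "hb_form": ("-", str),
    "combinatorial_form": ("-", str),
    "combinatorial_z": ("-", float),
    "version": ("-", str),
}


def save_params(params: InteractionParams, path: str | Path) -> None:
    """Write a parameter file that :func:`load_params` inverts bit-exactly."""
    lines = ["# descosmo interaction parameters"]
    for name, (unit, typ) in _PARAM_FIELDS.items():
        value = getattr(params, name)
        rendered = repr(value) if typ is float else str(value)
        lines.append(f"{name} {rendered}  # [{unit}]")
    Path(path).write_text("\n".join(lines) + "\n")


def load_params(path: str | Path) -> InteractionParams:
    """Load a flat key-value parameter file written by :func:`save_params`."""
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            name, value = line.split(None, 1)
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: malformed parameter line")
        if name not in _PARAM_FIELDS:
            raise ValidationError(f"{path}:{lineno}: unknown parameter {name!r}")
        _, typ = _PARAM_FIELDS[name]
        kwargs[name] = typ(value)
    return InteractionParams(**kwargs)


def default_params() -> InteractionParams:
    """The shipped, versioned default parameter set."""
    ref = resources.files("descosmo.data").joinpath("params_default.txt")
    with resources.as_file(ref) as path:
        return load_params(path)
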