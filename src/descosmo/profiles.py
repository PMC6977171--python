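"""σ-grids, σ-profiles, species and solvent mixtures.

The σ-profile p(σ) is the central molecular descriptor of the segment
model: a histogram of a molecule's cavity surface area (Å²) binned by the
screening charge density σ (e/Å²) induced on that surface in a perfect
conductor.  Negative σ marks surface patches over positive partial charges
(hydrogen-bond donor hydrogens), positive σ marks patches over lone pairs
(acceptors).  Everything downstream — the σ-potential, chemical potentials,
solubility — consumes these histograms.

Profiles are stored *area-weighted* (Å² per bin); normalization to a
probability distribution is explicit via :func:`normalize_profile`.
Mixture profiles follow the mole-fraction-weighted sum over components.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    DegenerateInputError,
    GridMismatchError,
    ProfileParseError,
    SigmaRangeError,
    ValidationError,
)

__all__ = [
    "SigmaGrid",
    "SigmaProfile",
    "Species",
    "SolventMixture",
    "read_sigma_profile",
    "write_sigma_profile",
    "read_species_table",
    "normalize_profile",
    "mix_profiles",
]

_GRID_TOL = 1e-12


@dataclass(frozen=True)
class SigmaGrid:
    """Uniform, zero-centred grid of screening charge densities (e/Å²).

    The default −0.030 … +0.030 e/Å² axis with 0.001 step (61 points) is the
    conventional axis on which σ-profiles are tabulated.
    """

    sigma_min: float = -0.030
    sigma_max: float = 0.030
    n_bins: int = 61

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValidationError("grid needs at least 3 bins")
        if not self.sigma_min < 0.0 < self.sigma_max:
            raise ValidationError("grid must straddle σ = 0")
        if abs(self.sigma_min + self.sigma_max) > _GRID_TOL:
            raise ValidationError("grid must be symmetric about σ = 0")
        step = self.step
        # zero must be a grid point: symmetric grid => odd bin count
        if self.n_bins % 2 == 0:
            raise ValidationError("symmetric grid containing σ=0 needs an odd n_bins")
        span = self.sigma_max - self.sigma_min
        if abs(span - (self.n_bins - 1) * step) > 1e-12:
            raise ValidationError("grid spacing is not uniform")

    @property
    def step(self) -> float:
        return (self.sigma_max - self.sigma_min) / (self.n_bins - 1)

    @property
    def values(self) -> np.ndarray:
        """Grid points σ_k, shape (n_bins,)."""
        return np.linspace(self.sigma_min, self.sigma_max, self.n_bins)

    def index_of_zero(self) -> int:
        return (self.n_bins - 1) // 2

    def locate(self, sigma: float) -> tuple[int, int, float]:
        """Bracketing bins and left-bin weight for an arbitrary σ.

        Returns ``(k_lo, k_hi, w_lo)`` such that depositing area ``A`` as
        ``w_lo·A`` in bin ``k_lo`` and ``(1−w_lo)·A`` in ``k_hi`` conserves
        both area and the first moment (linear apportionment).
        """
        if not (self.sigma_min - _GRID_TOL <= sigma <= self.sigma_max + _GRID_TOL):
            raise SigmaRangeError(
                f"σ = {sigma:g} outside grid [{self.sigma_min:g}, {self.sigma_max:g}]"
            )
        t = (sigma - self.sigma_min) / self.step
        # snap to a grid point when within float round-off of one, so that
        # on-grid σ values land in a single bin (exact read/write inversion)
        nearest = round(t)
        if 0 <= nearest <= self.n_bins - 1 and abs(t - nearest) < 1e-9:
            k_lo = int(min(nearest, self.n_bins - 2))
            return k_lo, k_lo + 1, 1.0 if k_lo == nearest else 0.0
        k_lo = int(np.clip(np.floor(t), 0, self.n_bins - 2))
        frac = t - k_lo
        return k_lo, k_lo + 1, 1.0 - frac


@dataclass
class SigmaProfile:
    """Area-weighted σ-histogram: ``area_per_bin[k]`` Å² of surface at σ_k."""

    grid: SigmaGrid
    area_per_bin: np.ndarray

    def __post_init__(self) -> None:
        self.area_per_bin = np.asarray(self.area_per_bin, dtype=float)
        if self.area_per_bin.shape != (self.grid.n_bins,):
            raise ValidationError(
                f"area_per_bin has shape {self.area_per_bin.shape}, "
                f"expected ({self.grid.n_bins},)"
            )
        if np.any(self.area_per_bin < 0):
            raise ValidationError("negative segment area in profile")
        if not np.all(np.isfinite(self.area_per_bin)):
            raise ValidationError("non-finite segment area in profile")

    @property
    def total_area(self) -> float:
        """Total cavity surface area, Å²."""
        return float(self.area_per_bin.sum())

    def require_physical(self) -> None:
        if self.total_area <= 0.0:
            raise DegenerateInputError("profile has zero total area")

    def same_grid(self, other: "SigmaProfile") -> bool:
        return self.grid == other.grid


@dataclass
class Species:
    """A molecular species: name, molar mass and its σ-profile.

    ``gibbs_fusion`` is the free energy of fusion ΔG_fus (kJ/mol) at the
    reference temperature — the solid-state penalty in the solubility
    equation.  It is ``None`` for liquids and may be left ``None`` for
    solids when only relative solubilities (where it cancels) are needed.
    """

    name: str
    molar_mass: float
    profile: SigmaProfile
    cosmo_volume: float | None = None
    gibbs_fusion: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValidationError(f"{self.name}: molar mass must be positive")
        if self.gibbs_fusion is not None and self.gibbs_fusion < 0:
            raise ValidationError(f"{self.name}: ΔG_fus must be ≥ 0")

    @property
    def cosmo_area(self) -> float:
        """Cavity surface area (Å²) — identically the profile's total area."""
        return self.profile.total_area


@dataclass
class SolventMixture:
    """Ordered components with mole fractions summing to one.

    Every component of a multicomponent solvent (each DES constituent,
    water included) is an independent mole-bearing species; a 1:0.9:0.6
    molar-ratio DES contributes 2.5 mol of particles per formula set.
    """

    components: Sequence[tuple[Species, float]]
    label: str | None = None

    def __post_init__(self) -> None:
        comps = list(self.components)
        if not comps:
            raise ValidationError("mixture needs at least one component")
        names = [sp.name for sp, _ in comps]
        if len(set(names)) != len(names):
            raise ValidationError("component names must be unique")
        fracs = np.array([x for _, x in comps], dtype=float)
        if np.any(fracs < 0):
            raise ValidationError("mole fractions must be ≥ 0")
        if abs(fracs.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"mole fractions sum to {fracs.sum():.15g}, expected 1"
            )
        self.components = [(sp, float(x)) for sp, x in comps]

    @classmethod
    def from_ratios(
        cls,
        species_ratios: Iterable[tuple[Species, float]],
        label: str | None = None,
    ) -> "SolventMixture":
        """Build from molar ratios (e.g. Table-style 1:0.9:0.6 stoichiometry)."""
        pairs = list(species_ratios)
        total = sum(r for _, r in pairs)
        if total <= 0:
            raise ValidationError("molar ratios must sum to a positive value")
        return cls([(sp, r / total) for sp, r in pairs], label=label)

    @classmethod
    def pure(cls, species: Species, label: str | None = None) -> "SolventMixture":
        return cls([(species, 1.0)], label=label or species.name)

    @property
    def names(self) -> list[str]:
        return [sp.name for sp, _ in self.components]

    @property
    def display_name(self) -> str:
        return self.label or "+".join(self.names)

    def mean_cosmo_area(self) -> float:
        """Mole-fraction-weighted mean cavity area, Å²."""
        return float(sum(x * sp.cosmo_area for sp, x in self.components))

    def mean_cosmo_volume(self) -> float | None:
        vols = [(sp.cosmo_volume, x) for sp, x in self.components]
        if any(v is None for v, _ in vols):
            return None
        return float(sum(x * v for v, x in vols))


def read_sigma_profile(
    path: str | Path | io.TextIOBase,
    grid: SigmaGrid | None = None,
    dialect: str = "vt2005",
) -> SigmaProfile:
    """Read a two-column (σ, area) profile file onto the canonical grid.

    The accepted dialect is the plain-text community format: whitespace-
    separated columns ``sigma[e/Å²] area[Å²]``, ``#`` comments.  Rows whose
    σ falls between grid points are apportioned linearly to the two
    bracketing bins, which conserves total area.
    """
    if dialect != "vt2005":
        raise ValidationError(f"unknown σ-profile dialect {dialect!r}")
    grid = grid or SigmaGrid()
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        source = str(path)
    else:
        text = path.read()
        source = "<stream>"

    areas = np.zeros(grid.n_bins)
    prev_sigma = None
    saw_row = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ProfileParseError(
                f"{source}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        try:
            sigma, area = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ProfileParseError(f"{source}:{lineno}: non-numeric field") from exc
        if prev_sigma is not None and sigma <= prev_sigma:
            raise ProfileParseError(
                f"{source}:{lineno}: σ column must be strictly increasing"
            )
        prev_sigma = sigma
        if area < 0:
            raise ValidationError(f"{source}:{lineno}: negative area {area:g}")
        k_lo, k_hi, w_lo = grid.locate(sigma)
        areas[k_lo] += w_lo * area
        areas[k_hi] += (1.0 - w_lo) * area
        saw_row = True
    if not saw_row:
        raise ProfileParseError(f"{source}: no data rows")
    return SigmaProfile(grid, areas)


def write_sigma_profile(profile: SigmaProfile, path: str | Path) -> None:
    """Write a profile as full-precision two-column text (read inverts it)."""
    profile.require_physical()
    lines = ["# sigma[e/A^2]  area[A^2]"]
    for sigma, area in zip(profile.grid.values, profile.area_per_bin):
        lines.append(f"{sigma:.6f} {float(area)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_species_table(
    path: str | Path, grid: SigmaGrid | None = None
) -> dict[str, Species]:
    """Read a delimited species-metadata table and its σ-profile files.

    Columns (comma-separated, ``#`` comments): ``name``, ``molar_mass``
    [g/mol], ``cosmo_volume`` [Å³, optional], ``gibbs_fusion`` [kJ/mol,
    optional, empty for liquids], ``profile_path`` (relative to the
    table's directory).
    """
    import csv as _csv

    path = Path(path)
    grid = grid or SigmaGrid()
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    species: dict[str, Species] = {}
    for row in _csv.DictReader(lines):
        name = row["name"].strip()
        profile = read_sigma_profile(path.parent / row["profile_path"].strip(), grid)
        volume = float(row["cosmo_volume"]) if row.get("cosmo_volume") else None
        dgfus = float(row["gibbs_fusion"]) if row.get("gibbs_fusion") else None
        species[name] = Species(
            name=name,
            molar_mass=float(row["molar_mass"]),
            profile=profile,
            cosmo_volume=volume,
            gibbs_fusion=dgfus,
        )
    return species


def normalize_profile(profile: SigmaProfile) -> np.ndarray:
    """Probability weights per bin, proportional to area; sums to 1."""
    profile.require_physical()
    w = profile.area_per_bin / profile.area_per_bin.sum()
    return w / w.sum()  # second pass pins the sum to 1 within 1e-12


def mix_profiles(mixture: SolventMixture) -> SigmaProfile:
    """Mole-fraction-weighted mixture σ-profile.

    p_mix(σ) = Σ_i x_i·p_i(σ); the mixture total area is then the
    mole-fraction-weighted mean of the component areas.
    """
    first = mixture.components[0][0].profile
    areas = np.zeros(first.grid.n_bins)
    for sp, x in mixture.components:
        if sp.profile.grid != first.grid:
            raise GridMismatchError(
                f"component {sp.name!r} is on a different σ-grid"
            )
        areas += x * sp.profile.area_per_bin
    return SigmaProfile(first.grid, areas)
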