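"""Solvent-system bookkeeping and solubility unit arithmetic.

Everything needed to move between the units in which solubility is
measured (mg API per g solvent) and the units in which the thermodynamic
model speaks (mole fraction): molar compositions of the solvent systems,
mean molar masses, mg/g ↔ mole-fraction conversion, fold ratios,
log10-unit differences, and hydrate water mass fractions.

The packaged fixtures carry the study design: six deep eutectic solvents
(choline chloride–urea 1:2, choline chloride–glycerol 1:2, choline
chloride–lactic acid–water 1:0.9:0.6, betaine–glycerol–water 1:2:1,
choline chloride–glucose–water 1:0.4:1, lactic acid–glucose–water
1:0.2:1.2), water, three conventional pharmaceutical solvents (ethanol,
glycerol, PEG 300), and the triplicate 24 h shake-flask solubilities of
11 APIs in each — 110 cells, each a (mean, sd) pair or an explicit flag —
plus lactic-acid-alone measurements for three APIs.

Mole-fraction convention: every component of a multicomponent solvent is
an independent mole-bearing species (a 1:0.9:0.6 system carries 2.5 mol
of particles per formula set).  ``mole_basis="ratio"`` switches the
conversion to a per-formula-set basis for sensitivity checks.
"""

from __future__ import annotations

import csv
import hashlib
import io
import math
from dataclasses import dataclass
from importlib import resources

from .exceptions import (
    FixtureIntegrityError,
    UndefinedResultError,
    ValidationError,
)

__all__ = [
    "CompositionSpec",
    "SolubilityRecord",
    "mean_molar_mass",
    "mg_per_g_to_mole_fraction",
    "mole_fraction_to_mg_per_g",
    "fold_ratio",
    "log10_units_difference",
    "water_mass_fraction",
    "load_fixtures",
    "record_lookup",
    "api_molar_masses",
    "GRID_SOLVENTS",
    "GRID_APIS",
]

#: Solvent labels of the full measurement grid, in presentation order.
GRID_SOLVENTS = (
    "CU", "CG", "CLW", "BGW", "LGluW", "CGluW",
    "Ethanol", "Glycerol", "PEG300", "Water",
)

#: APIs of the study, in presentation order.
GRID_APIS = (
    "naproxen", "paracetamol", "ibuprofen", "flufenamic acid", "indomethacin",
    "lidocaine", "theophylline", "celecoxib", "aprepitant", "probucol",
    "cinnarizine",
)

#: Common shorthand for the two glucose DESs.
SOLVENT_ALIASES = {"LGW": "LGluW", "CGW": "CGluW"}

_FIXTURE_SHA256 = {
    "compositions.csv": "aca9370d8341c5a17ba4974cccff02ec699f3a07c15f8244414a711e29dae58b",
    "solubilities.csv": "8b21759bcfde62676fca1a7d249397f87c87fea357cd287937aab2e6b610a693",
}

_KNOWN_FLAGS = {"below_LOQ", "viscous", "phase_separation"}


@dataclass(frozen=True)
class CompositionSpec:
    """A named solvent system as (component, molar mass, molar ratio) rows."""

    label: str
    components: tuple[tuple[str, float, float], ...]
    role: str = "des"

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError(f"{self.label}: needs at least one component")
        for name, mass, ratio in self.components:
            if mass <= 0:
                raise ValidationError(f"{self.label}/{name}: molar mass must be > 0")
            if ratio <= 0:
                raise ValidationError(f"{self.label}/{name}: molar ratio must be > 0")


@dataclass(frozen=True)
class SolubilityRecord:
    """One measured solubility cell: mean ± sd in mg API per g solvent."""

    api_name: str
    solvent_label: str
    mean: float | None = None
    sd: float | None = None
    n: int = 3
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if "below_LOQ" in self.flags and self.mean is not None:
            raise ValidationError("below_LOQ records carry no mean")
        if self.mean is not None and self.mean < 0:
            raise ValidationError("mean solubility must be ≥ 0")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be ≥ 0")
        unknown = self.flags - _KNOWN_FLAGS
        if unknown:
            raise ValidationError(f"unknown flags {sorted(unknown)}")

    @property
    def quantified(self) -> bool:
        return self.mean is not None


def mean_molar_mass(spec: CompositionSpec) -> float:
    """Mole-weighted mean molar mass, g/mol: Σ(r_i·M_i)/Σ r_i.

    Scale-invariant in the molar ratios.
    """
    total_ratio = sum(r for _, _, r in spec.components)
    return sum(r * m for _, m, r in spec.components) / total_ratio


def mg_per_g_to_mole_fraction(
    mg_per_g: float,
    solute_molar_mass: float,
    spec: CompositionSpec,
    mole_basis: str = "component",
) -> float:
    """Convert mg solute per g solvent to mole-fraction solubility.

    x = n_API / (n_API + n_solvent) per gram of solvent, with
    n_solvent = 1/M̄ and M̄ the mean molar mass of the solvent system.
    ``mole_basis="component"`` counts every mixture component as
    mole-bearing (default); ``"ratio"`` counts whole formula sets.
    """
    if mg_per_g < 0:
        raise ValidationError("mg_per_g must be ≥ 0")
    if solute_molar_mass <= 0:
        raise ValidationError("solute molar mass must be > 0")
    m_bar = _basis_molar_mass(spec, mole_basis)
    n_api = (mg_per_g / 1000.0) / solute_molar_mass
    n_solvent = 1.0 / m_bar
    return n_api / (n_api + n_solvent)


def mole_fraction_to_mg_per_g(
    x: float,
    solute_molar_mass: float,
    spec: CompositionSpec,
    mole_basis: str = "component",
) -> float:
    """Inverse of :func:`mg_per_g_to_mole_fraction` (round-trip identity)."""
    if not 0.0 <= x < 1.0:
        raise ValidationError("mole fraction must lie in [0, 1)")
    m_bar = _basis_molar_mass(spec, mole_basis)
    n_api_per_g = (x / (1.0 - x)) / m_bar
    return n_api_per_g * solute_molar_mass * 1000.0


def _basis_molar_mass(spec: CompositionSpec, mole_basis: str) -> float:
    if mole_basis == "component":
        return mean_molar_mass(spec)
    if mole_basis == "ratio":
        # one mole of solvent = one formula set (pseudo-molecule convention)
        return float(sum(r * m for _, m, r in spec.components))
    raise ValidationError(f"unknown mole_basis {mole_basis!r}")


def fold_ratio(a: float, b: float, rounding: str = "none") -> float:
    """Solubility ratio a/b with a stated rounding convention.

    ``rounding``: ``one_decimal``, ``nearest_integer``, ``none``, or
    ``auto`` (one decimal below 10, nearest integer at ≥ 10 — the usual
    way fold improvements are quoted).
    """
    if a is None or b is None:
        raise UndefinedResultError("fold ratio undefined for below-LOQ operands")
    if b == 0:
        raise ZeroDivisionError("fold ratio with zero denominator")
    ratio = a / b
    if rounding == "auto":
        rounding = "nearest_integer" if ratio >= 10 else "one_decimal"
    if rounding == "one_decimal":
        return round(ratio, 1)
    if rounding == "nearest_integer":
        return float(round(ratio))
    if rounding == "none":
        return ratio
    raise ValidationError(f"unknown rounding {rounding!r}")


def log10_units_difference(x_a: float, x_b: float) -> float:
    """log10(x_a) − log10(x_b): solubility difference in log units."""
    if x_a <= 0 or x_b <= 0:
        raise ValidationError("log-unit difference needs positive mole fractions")
    return math.log10(x_a) - math.log10(x_b)


def water_mass_fraction(
    formula_components: list[tuple[str, float, float]]
) -> float:
    """Water weight percent of a (hydrate) formula.

    ``formula_components`` is (name, molar_mass g/mol, count per formula
    unit); water is recognized by name.  E.g. sodium tartrate dihydrate →
    15.7 wt%, the Karl Fischer titer standard.
    """
    total = sum(count * m for _, m, count in formula_components)
    if total <= 0:
        raise ValidationError("formula must have positive mass")
    water = sum(
        count * m
        for name, m, count in formula_components
        if name.strip().lower() in ("water", "h2o")
    )
    return 100.0 * water / total


# ---------------------------------------------------------------------------
# Packaged fixtures

def _read_fixture_text(filename: str, verify_checksum: bool = True) -> str:
    ref = resources.files("descosmo.data").joinpath(filename)
    data = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        if digest != _FIXTURE_SHA256[filename]:
            raise FixtureIntegrityError(
                f"{filename}: sha256 {digest} does not match the packaged value"
            )
    return data.decode("utf-8")


def load_fixtures(
    verify_checksum: bool = True,
) -> tuple[list[CompositionSpec], list[SolubilityRecord]]:
    """Load the packaged solvent compositions and solubility table.

    Verifies file checksums and asserts the full 11-API × 10-solvent grid
    is present, every cell either quantified or explicitly flagged.
    """
    specs = _load_compositions(verify_checksum)
    records = _load_solubilities(verify_checksum)
    _check_completeness(specs, records)
    return specs, records


def _load_compositions(verify_checksum: bool) -> list[CompositionSpec]:
    text = _read_fixture_text("compositions.csv", verify_checksum)
    rows = _csv_rows(text)
    by_label: dict[str, dict] = {}
    for row in rows:
        entry = by_label.setdefault(row["label"], {"role": row["role"], "parts": []})
        if entry["role"] != row["role"]:
            raise FixtureIntegrityError(f"{row['label']}: inconsistent role")
        entry["parts"].append(
            (row["component"], float(row["molar_mass"]), float(row["molar_ratio"]))
        )
    return [
        CompositionSpec(label, tuple(e["parts"]), role=e["role"])
        for label, e in by_label.items()
    ]


def _load_solubilities(verify_checksum: bool) -> list[SolubilityRecord]:
    text = _read_fixture_text("solubilities.csv", verify_checksum)
    records = []
    for row in _csv_rows(text):
        flags = frozenset(f for f in row["flags"].split(";") if f)
        mean = float(row["mean"]) if row["mean"] else None
        sd = float(row["sd"]) if row["sd"] else None
        solvent = SOLVENT_ALIASES.get(row["solvent"], row["solvent"])
        records.append(
            SolubilityRecord(
                api_name=row["api"],
                solvent_label=solvent,
                mean=mean,
                sd=sd,
                n=int(row["n"]),
                flags=flags,
            )
        )
    return records


def _csv_rows(text: str) -> list[dict]:
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return list(csv.DictReader(io.StringIO("\n".join(lines))))


def _check_completeness(
    specs: list[CompositionSpec], records: list[SolubilityRecord]
) -> None:
    labels = {s.label for s in specs}
    missing_specs = set(GRID_SOLVENTS) - labels
    if missing_specs:
        raise FixtureIntegrityError(f"missing composition specs: {sorted(missing_specs)}")
    n_des = sum(1 for s in specs if s.role == "des")
    n_single = sum(1 for s in specs if s.role in ("conventional", "water"))
    if n_des != 6 or n_single != 4:
        raise FixtureIntegrityError(
            f"expected 6 DES + 4 single-solvent specs, found {n_des} + {n_single}"
        )
    cells = {(r.api_name, r.solvent_label) for r in records}
    expected = {(a, s) for a in GRID_APIS for s in GRID_SOLVENTS}
    missing = expected - cells
    if missing:
        raise FixtureIntegrityError(
            f"{len(missing)} missing solubility cells, e.g. {sorted(missing)[:3]}"
        )
    for r in records:
        if not r.quantified and not r.flags:
            raise FixtureIntegrityError(
                f"{r.api_name}/{r.solvent_label}: neither value nor flag"
            )


def record_lookup(
    records: list[SolubilityRecord],
) -> dict[tuple[str, str], SolubilityRecord]:
    """Index records by (api, solvent)."""
    return {(r.api_name, r.solvent_label): r for r in records}


def api_molar_masses(verify_checksum: bool = True) -> dict[str, float]:
    """API molar masses (g/mol) as bundled in the solubility fixture."""
    text = _read_fixture_text("solubilities.csv", verify_checksum)
    return {row["api"]: float(row["api_molar_mass"]) for row in _csv_rows(text)}
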