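"""Configured end-to-end study runs.

A study config is a single YAML file describing either a *real* study
(species table + solvent composition strings) or a *synthetic* one
(generator settings).  ``run_study`` executes the workflow — predictions
for every (solute, solvent) pair, per-solute solvent rankings, and, when
an experimental table is supplied (or generated), comparison statistics
and a relative-solubility table — and writes everything as delimited
text into the output directory, together with an echo of the config for
provenance.  Outputs are deterministic for a fixed config.

Config schema (keys at top level)::

    output_dir: path            # required
    params_file: path           # optional; defaults to shipped parameters
    mode: dilute | iterative    # default dilute
    reference: solvent-name     # optional; enables relative predictions
    species_table: path         # real study
    solutes: [name, ...]
    solvents: ["water", "cc:urea=1:2", ...]
    experimental_table: path    # optional TSV: api, solvent, log10_x
    synthetic:                  # alternative to species_table
      seed: int                 # required for any stochastic path
      n_solutes: int
      n_solvents: int
      noise_sd: float
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .analytics import linear_fit_stats, per_api_rank_agreement
from .exceptions import InsufficientDataError, ValidationError
from .interactions import InteractionParams, default_params, load_params, save_params
from .profiles import read_species_table
from .solubility import (
    LN10,
    ln_solubility_dilute,
    ln_solubility_iterative,
    rank_solvents,
)
from .synthetic import SyntheticSpec, synthetic_study

__all__ = ["RunConfig", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated study configuration (see module docstring for the schema)."""

    output_dir: str
    params_file: str | None = None
    mode: str = "dilute"
    reference: str | None = None
    species_table: str | None = None
    solutes: list[str] | None = None
    solvents: list[str] | None = None
    experimental_table: str | None = None
    synthetic: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dilute", "iterative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if (self.species_table is None) == (self.synthetic is None):
            raise ValidationError(
                "config must provide exactly one of species_table / synthetic"
            )
        if self.synthetic is not None and "seed" not in self.synthetic:
            raise ValidationError("synthetic study requires an explicit seed")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError("config file must contain a mapping")
        return cls(**raw)


def run_study(config: RunConfig | str | Path) -> Path:
    """Execute a configured study and return the report directory."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    params = load_params(config.params_file) if config.params_file else default_params()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        predictions, experiments = _synthetic_stage(config, params, outdir)
    else:
        predictions = _prediction_stage(config, params)
        experiments = (
            _read_pair_table(config.experimental_table)
            if config.experimental_table
            else None
        )

    _write_pair_table(outdir / "predictions.tsv", predictions)
    _write_rankings(outdir / "rankings.tsv", predictions)
    if experiments is not None:
        _comparison_stage(outdir, predictions, experiments)

    # provenance echo
    save_params(params, outdir / "params_used.txt")
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True)
    )
    return outdir


def _synthetic_stage(config: RunConfig, params: InteractionParams, outdir: Path):
    spec = SyntheticSpec(**config.synthetic)
    study = synthetic_study(spec, params)
    predictions = dict(study.true_log10_x)
    experiments = study.experimental_log10_x()
    with open(outdir / "synthetic_experimental_mg_per_g.tsv", "w") as fh:
        fh.write("api\tsolvent\tmean\tsd\n")
        for r in study.experimental_records:
            fh.write(f"{r.api_name}\t{r.solvent_label}\t{r.mean!r}\t{r.sd!r}\n")
    return predictions, experiments


def _prediction_stage(config: RunConfig, params: InteractionParams):
    from .cli import _parse_solvent  # shared composition-string parser

    if not config.solutes or not config.solvents:
        raise ValidationError("real study config needs solutes and solvents lists")
    species = read_species_table(config.species_table)
    missing = [n for n in config.solutes if n not in species]
    if missing:
        raise ValidationError(f"unknown solutes {missing}")
    solvents = [_parse_solvent(d, species) for d in config.solvents]
    predict = ln_solubility_dilute if config.mode == "dilute" else ln_solubility_iterative
    predictions: dict[tuple[str, str], float] = {}
    for name in config.solutes:
        sp = species[name]
        dg = sp.gibbs_fusion if sp.gibbs_fusion is not None else 0.0
        for sv in solvents:
            rec = predict(sp, sv, params, dg)
            if not rec.converged:
                logger.warning("%s/%s: not converged", name, sv.display_name)
            predictions[(name, sv.display_name)] = rec.ln_x / LN10
    return predictions


def _comparison_stage(outdir: Path, predictions, experiments) -> None:
    keys = sorted(set(predictions) & set(experiments))
    if not keys:
        raise ValidationError("no overlapping (api, solvent) pairs to compare")
    stats = linear_fit_stats(
        [predictions[k] for k in keys], [experiments[k] for k in keys]
    )
    lines = ["statistic\tvalue"]
    for name in ("slope", "intercept", "r_squared", "rmse", "spearman_rho", "n"):
        lines.append(f"{name}\t{getattr(stats, name)!r}")
    apis = sorted({a for a, _ in keys})
    for api in apis:
        try:
            rho = per_api_rank_agreement(predictions, experiments, api)
        except InsufficientDataError as exc:
            logger.info("rank agreement skipped: %s", exc)
            continue
        lines.append(f"spearman[{api}]\t{rho!r}")
    (outdir / "comparison.tsv").write_text("\n".join(lines) + "\n")


def _read_pair_table(path) -> dict[tuple[str, str], float]:
    out = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("api\t"):
            continue
        api, solvent, value = ln.split("\t")
        out[(api, solvent)] = float(value)
    return out


def _write_pair_table(path: Path, table) -> None:
    with open(path, "w") as fh:
        fh.write("api\tsolvent\tlog10_x\n")
        for (api, solvent), v in sorted(table.items()):
            fh.write(f"{api}\t{solvent}\t{v!r}\n")


def _write_rankings(path: Path, predictions) -> None:
    apis = sorted({a for a, _ in predictions})
    with open(path, "w") as fh:
        fh.write("api\trank\tsolvent\tlog10_x\n")
        for api in apis:
            rows = sorted(
                ((s, v) for (a, s), v in predictions.items() if a == api),
                key=lambda kv: (-kv[1], kv[0]),
            )
            for i, (s, v) in enumerate(rows, start=1):
                fh.write(f"{api}\t{i}\t{s}\t{v!r}\n")
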