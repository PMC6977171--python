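"""Predicted-vs-experimental comparison statistics.

Given paired log-solubilities — model predictions and measurements keyed
by (API, solvent) — this module computes the summary statistics used to
judge a screening model: ordinary least-squares fit of experiment on
prediction (slope, intercept, R², RMSE of the fit residuals), Spearman
rank correlation over all pairs, per-API rank agreement across solvents,
and log10 relative-solubility tables against a per-API reference solvent.

Below-LOQ experimental cells are excluded from every statistic, never
imputed; exclusions are counted and reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError

__all__ = [
    "ComparisonStats",
    "linear_fit_stats",
    "per_api_rank_agreement",
    "relative_solubility_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonStats:
    """OLS fit of experimental on predicted log-solubility, plus rank stats."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float
    spearman_rho: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError("comparison needs at least 2 points")


def linear_fit_stats(predicted, experimental) -> ComparisonStats:
    """Regress experimental log-solubility on predicted and summarize.

    RMSE is the root-mean-square of the fit residuals; R² is the squared
    Pearson correlation of the two vectors (identical to the OLS R²).
    The statistics are invariant to a common additive shift of both
    vectors — the comparison lives on a log scale where only differences
    matter.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("predicted/experimental must be equal-length 1-D")
    mask = np.isfinite(x) & np.isfinite(y)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("linear_fit_stats: dropped %d non-finite pairs", dropped)
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise InsufficientDataError(f"only {x.size} valid pairs")
    if np.ptp(x) == 0.0:
        raise InsufficientDataError("predicted values are constant; no fit possible")
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    r_squared = float(fit.rvalue**2)
    if np.ptp(y) == 0.0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return ComparisonStats(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        rmse=rmse,
        spearman_rho=rho,
        n=int(x.size),
    )


def per_api_rank_agreement(
    predictions: dict[tuple[str, str], float],
    experiments: dict[tuple[str, str], float],
    api: str,
) -> float:
    """Spearman ρ of predicted vs. experimental solvent ranks for one API.

    Uses the solvents for which both a prediction and a quantified
    measurement exist (≥ 3 required); ties receive mid-ranks.
    """
    solvents = sorted(
        {s for (a, s) in predictions if a == api}
        & {s for (a, s) in experiments if a == api}
    )
    pred = [predictions[(api, s)] for s in solvents]
    expt = [experiments[(api, s)] for s in solvents]
    pairs = [(p, e) for p, e in zip(pred, expt) if math.isfinite(p) and math.isfinite(e)]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"{api}: only {len(pairs)} solvents with paired values"
        )
    p, e = zip(*pairs)
    return float(stats.spearmanr(p, e).statistic)


def relative_solubility_table(
    predictions: dict[tuple[str, str], float],
    experiments: dict[tuple[str, str], float],
    reference_map: dict[str, str],
) -> list[tuple[str, str, float, float]]:
    """Pair experimental and predicted log10 solubility relative to a reference.

    ``predictions`` and ``experiments`` map (API, solvent) to log10
    absolute solubility (any common offset per API cancels).
    ``reference_map`` assigns each API its reference solvent — typically
    water, with ethanol substituted where the aqueous solubility was
    unquantifiable.  Returns rows (api, solvent, experimental_rel,
    predicted_rel); solvent == reference rows are omitted, and APIs or
    cells without both values and a reference are skipped with a log
    entry.
    """
    rows = []
    for (api, solvent), expt in sorted(experiments.items()):
        ref = reference_map.get(api)
        if ref is None:
            logger.info("relative table: %s has no reference solvent; skipped", api)
            continue
        if solvent == ref:
            continue
        ref_expt = experiments.get((api, ref))
        pred = predictions.get((api, solvent))
        ref_pred = predictions.get((api, ref))
        values = (expt, ref_expt, pred, ref_pred)
        if any(v is None or not math.isfinite(v) for v in values):
            logger.info(
                "relative table: %s/%s skipped (missing value or reference)",
                api,
                solvent,
            )
            continue
        rows.append((api, solvent, expt - ref_expt, pred - ref_pred))
    return rows
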