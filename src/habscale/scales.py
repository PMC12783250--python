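"""Per-predictor scale optimization and collinearity screening.

Species–habitat relationships are scale-dependent: each predictor is
evaluated at every smoothing scale of the ladder with a univariate
logistic regression, and the scale with the strongest likelihood (lowest
AIC; both fits have k = 2, so AIC ordering equals likelihood ordering)
is bound to that predictor. The chosen-scale columns are then screened
for pairwise correlation (|r| > 0.7 drops the higher-AIC member) and
for multicollinearity (VIF > 5 drops the worst column, iteratively).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .raster import ScaleSet, column_name

log = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class ScaleSelectionResult:
    """Chosen scale and per-scale univariate AICs for each predictor."""

    aic_by_scale: dict[str, dict[float, float]]
    chosen_scale: dict[str, float]
    chosen_aic: dict[str, float]
    flagged: list[tuple[str, float, str]] = field(default_factory=list)

    @property
    def predictors(self) -> list[str]:
        return sorted(self.chosen_scale)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for p, by_scale in sorted(self.aic_by_scale.items()):
            for s, aic in sorted(by_scale.items()):
                recs.append(
                    {
                        "predictor": p,
                        "scale_m": s,
                        "aic": aic,
                        "chosen": s == self.chosen_scale.get(p),
                    }
                )
        return pd.DataFrame.from_records(recs)


@dataclass
class CandidateSet:
    """Predictors retained after pruning, each bound to its chosen scale."""

    predictors: dict[str, float]
    chosen_aic: dict[str, float]
    removal_log: list[tuple[str, str, str]] = field(default_factory=list)

    def columns(self) -> list[str]:
        return [column_name(p, s) for p, s in sorted(self.predictors.items())]

    def __len__(self) -> int:
        return len(self.predictors)


def _univariate_aic(x: np.ndarray, y: np.ndarray) -> float:
    """AIC (-2 loglik + 4) of an intercept+slope logistic fit; raises
    PerfectSeparationError when the likelihood is unbounded."""
    X = sm.add_constant(np.asarray(x, dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        res = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0, method="newton", maxiter=100)
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e6:
        raise PerfectSeparationError("diverging univariate fit")
    return float(-2.0 * res.llf + 4.0)


def univariate_scale_scan(
    values: pd.DataFrame,
    response: pd.Series | np.ndarray,
    scales: ScaleSet,
    predictors: list[str] | None = None,
) -> ScaleSelectionResult:
    """Choose, per predictor, the smoothing scale whose univariate
    logistic model has the lowest AIC (ties break to the smallest scale).

    ``values`` holds one column per (predictor, scale), named by
    :func:`habscale.raster.column_name`. Scales with complete separation
    are flagged and excluded from the minimum.
    """
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise SelectionError("response must contain both classes")
    if predictors is None:
        predictors = sorted({c.rpartition("@")[0] for c in values.columns})
    aic_by_scale: dict[str, dict[float, float]] = {}
    chosen_scale: dict[str, float] = {}
    chosen_aic: dict[str, float] = {}
    flagged: list[tuple[str, float, str]] = []
    for p in predictors:
        by_scale: dict[float, float] = {}
        for s in scales:
            col = column_name(p, s)
            if col not in values.columns:
                raise SelectionError(f"missing value column {col!r}")
            try:
                by_scale[s] = _univariate_aic(values[col].to_numpy(), y)
            except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
                flagged.append((p, s, str(exc)))
                log.warning("scale scan: %s at %g m flagged (%s)", p, s, exc)
        if not by_scale:
            raise SelectionError(f"every scale failed for predictor {p!r}")
        aic_by_scale[p] = by_scale
        best = min(sorted(by_scale), key=lambda s: by_scale[s])  # ties -> smallest scale
        chosen_scale[p] = best
        chosen_aic[p] = by_scale[best]
    return ScaleSelectionResult(aic_by_scale, chosen_scale, chosen_aic, flagged)


def prune_correlated(
    result: ScaleSelectionResult, values: pd.DataFrame, threshold: float = 0.7
) -> CandidateSet:
    """Drop one member of every over-correlated pair of chosen-scale columns.

    Pairs are resolved in descending |r| order, recomputing after each
    drop; the member with the higher univariate AIC is removed. Constant
    columns (undefined correlation) are dropped first, with a log entry.
    """
    kept = dict(result.chosen_scale)
    removal_log: list[tuple[str, str, str]] = []
    for p in list(kept):
        col = values[column_name(p, kept[p])]
        if float(np.nanstd(col)) == 0.0:
            removal_log.append((p, "correlation", "constant column, correlation undefined"))
            del kept[p]
    while len(kept) >= 2:
        preds = sorted(kept)
        mat = values[[column_name(p, kept[p]) for p in preds]].to_numpy(dtype=float)
        r = np.corrcoef(mat, rowvar=False)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        if abs(r[i, j]) <= threshold:
            break
        a, b = preds[i], preds[j]
        drop = a if result.chosen_aic[a] > result.chosen_aic[b] else b
        keep = b if drop == a else a
        removal_log.append(
            (drop, "correlation", f"|r|={abs(r[i, j]):.3f} with {keep}; higher univariate AIC")
        )
        del kept[drop]
    for entry in removal_log:
        log.info("prune_correlated: removed %s (%s)", entry[0], entry[2])
    return CandidateSet(
        predictors=kept,
        chosen_aic={p: result.chosen_aic[p] for p in kept},
        removal_log=removal_log,
    )


def vif_filter(
    candidates: CandidateSet, values: pd.DataFrame, threshold: float = 5.0
) -> CandidateSet:
    """Iteratively remove the largest-VIF column while any VIF exceeds
    the threshold. A single remaining candidate passes vacuously."""
    kept = dict(candidates.predictors)
    removal_log = list(candidates.removal_log)
    while len(kept) >= 2:
        preds = sorted(kept)
        cols = [column_name(p, kept[p]) for p in preds]
        X = values[cols].to_numpy(dtype=float)
        if X.shape[0] <= X.shape[1]:
            raise SelectionError(
                f"{X.shape[0]} rows cannot support a VIF check on {X.shape[1]} predictors"
            )
        design = sm.add_constant(X, has_constant="add")
        vifs = np.array(
            [variance_inflation_factor(design, k + 1) for k in range(len(preds))]
        )
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        drop = preds[worst]
        removal_log.append((drop, "vif", f"VIF={vifs[worst]:.2f}"))
        log.info("vif_filter: removed %s (VIF=%.2f)", drop, vifs[worst])
        del kept[drop]
    return CandidateSet(
        predictors=kept,
        chosen_aic={p: candidates.chosen_aic[p] for p in kept},
        removal_log=removal_log,
    )


def select_candidates(
    values: pd.DataFrame,
    response: pd.Series | np.ndarray,
    scales: ScaleSet,
    corr_threshold: float = 0.7,
    vif_threshold: float = 5.0,
) -> tuple[ScaleSelectionResult, CandidateSet]:
    """Run the scan → correlation prune → VIF filter chain."""
    result = univariate_scale_scan(values, response, scales)
    cand = prune_correlated(result, values, corr_threshold)
    cand = vif_filter(cand, values, vif_threshold)
    return result, cand
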