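"""Threshold-sweep classification metrics and Boyce-index validation.

A continuous suitability prediction is binarized at each of a grid of
thresholds; per threshold the confusion matrix yields sensitivity,
specificity, Cohen's kappa, the true skill statistic (TSS = sensitivity
+ specificity − 1) and the binary AUC of the thresholded classifier,
(sensitivity + specificity) / 2 — the only AUC computable from a single
confusion matrix. The continuous Boyce index checks calibration against
an independent presence-only point set: it is the Spearman correlation
between moving-window suitability midpoints and the predicted-to-expected
frequency ratio, so a well-calibrated model scores near +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr


class EvaluationError(ValueError):
    pass


@dataclass
class ThresholdMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def tss(self) -> float:
        """True skill statistic: sensitivity + specificity − 1."""
        return self.sensitivity + self.specificity - 1.0

    @property
    def auc(self) -> float:
        """Binary AUC of the thresholded classifier: (sens + spec) / 2."""
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def kappa(self) -> float:
        """Cohen's kappa from the confusion counts (0 when chance
        agreement is total, i.e. a constant classifier)."""
        n = self.tp + self.fp + self.tn + self.fn
        if n == 0:
            return float("nan")
        po = (self.tp + self.tn) / n
        pe = (
            (self.tp + self.fp) * (self.tp + self.fn)
            + (self.fn + self.tn) * (self.fp + self.tn)
        ) / (n * n)
        if pe == 1.0:
            return 0.0
        return (po - pe) / (1.0 - pe)


def confusion_counts(
    predictions: np.ndarray, truth: np.ndarray, threshold: float
) -> ThresholdMetrics:
    """Confusion counts classifying prediction >= threshold as presence."""
    pred = np.asarray(predictions, dtype=float) >= threshold
    obs = np.asarray(truth).astype(bool)
    return ThresholdMetrics(
        threshold=float(threshold),
        tp=int(np.sum(pred & obs)),
        fp=int(np.sum(pred & ~obs)),
        tn=int(np.sum(~pred & ~obs)),
        fn=int(np.sum(~pred & obs)),
    )


def metrics_from_rates(sensitivity: float, specificity: float) -> tuple[float, float]:
    """(TSS, binary AUC) implied by a sensitivity/specificity pair."""
    return sensitivity + specificity - 1.0, 0.5 * (sensitivity + specificity)


def sweep_thresholds(
    predictions: np.ndarray, truth: np.ndarray, n_thresholds: int = 30
) -> list[ThresholdMetrics]:
    """Metrics on the interior threshold grid t_i = i / (n_thresholds + 1),
    i = 1..n_thresholds (endpoints 0 and 1 are degenerate and excluded)."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth)
    if predictions.min() < 0 or predictions.max() > 1:
        raise EvaluationError("predictions must lie in [0, 1]")
    if len(np.unique(truth)) < 2:
        raise EvaluationError("truth must contain both classes")
    return [
        confusion_counts(predictions, truth, i / (n_thresholds + 1))
        for i in range(1, n_thresholds + 1)
    ]


def select_optimal_threshold(metrics: Sequence[ThresholdMetrics]) -> ThresholdMetrics:
    """The entry maximizing binary AUC; ties break to higher kappa, then
    lower threshold."""
    if not metrics:
        raise EvaluationError("empty metrics list")
    return max(metrics, key=lambda m: (m.auc, m.kappa, -m.threshold))


def select_best_replicate(optima: Sequence[ThresholdMetrics]) -> int:
    """Index of the replicate whose optimal-threshold metrics maximize
    binary AUC (ties to higher kappa, then the earliest replicate)."""
    if not optima:
        raise EvaluationError("no replicates to compare")
    best = 0
    for i in range(1, len(optima)):
        if (optima[i].auc, optima[i].kappa) > (optima[best].auc, optima[best].kappa):
            best = i
    return best


@dataclass
class BoyceResult:
    """Continuous Boyce index with its P/E curve."""

    index: float
    midpoints: np.ndarray
    predicted: np.ndarray  # P: fraction of validation points per window
    expected: np.ndarray  # E: fraction of background cells per window
    ratio: np.ndarray  # F = P/E over windows with E > 0
    ratio_midpoints: np.ndarray


def continuous_boyce(
    validation_values: np.ndarray,
    background_values: np.ndarray,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> BoyceResult:
    """Continuous Boyce index of a suitability map against independent
    presence points.

    Windows of width ``window_width`` × (max − min of the background
    suitability) slide their midpoints evenly across the background
    range; per window, P is the fraction of validation values inside and
    E the fraction of background values. The index is the Spearman rank
    correlation between F = P/E and the window midpoint, over windows
    with E > 0. Rank-based, hence invariant to monotone rescaling.
    """
    v = np.asarray(validation_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    v, b = v[np.isfinite(v)], b[np.isfinite(b)]
    if len(v) < 10:
        raise EvaluationError("need at least 10 validation points")
    lo, hi = float(b.min()), float(b.max())
    if hi - lo <= 0:
        raise EvaluationError("constant background: Boyce windows are undefined")
    width = window_width * (hi - lo)
    mids = np.linspace(lo, hi, n_windows)
    P = np.empty(n_windows)
    E = np.empty(n_windows)
    for i, m in enumerate(mids):
        a, z = m - width / 2.0, m + width / 2.0
        P[i] = np.mean((v >= a) & (v <= z))
        E[i] = np.mean((b >= a) & (b <= z))
    ok = E > 0
    F = P[ok] / E[ok]
    if ok.sum() < 2:
        raise EvaluationError("fewer than two windows with nonzero expected fraction")
    rho = spearmanr(mids[ok], F).statistic
    return BoyceResult(
        index=float(rho),
        midpoints=mids,
        predicted=P,
        expected=E,
        ratio=F,
        ratio_midpoints=mids[ok],
    )
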