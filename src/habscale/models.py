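"""Logistic model fitting, exhaustive subset search, and map prediction.

Predictor columns are z-standardized to the training mean and SD before
fitting, so coefficient magnitudes are comparable across predictors; the
standardization constants travel with the fitted model and are re-applied
when predicting a suitability surface. Models are ranked by AICc — the
small-sample Akaike criterion AIC + 2k(k+1)/(n−k−1) — with models inside
ΔAICc < 2 forming the support set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .raster import PredictorRaster, ScaledPredictorStack, split_column_name


class ModelError(ValueError):
    pass


class SeparationError(ModelError):
    """Complete separation: the likelihood has no finite maximizer."""


def standardize(values: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-standardize columns; returns the transformed frame and the
    per-column (mean, sd) constants."""
    consts: dict[str, tuple[float, float]] = {}
    out = {}
    for c in values.columns:
        v = values[c].to_numpy(dtype=float)
        mu, sd = float(np.mean(v)), float(np.std(v))
        if sd == 0.0:
            raise ModelError(f"column {c!r} is constant; cannot standardize")
        consts[c] = (mu, sd)
        out[c] = (v - mu) / sd
    return pd.DataFrame(out, index=values.index), consts


@dataclass
class FittedModel:
    """A fitted logistic regression with its selection statistics.

    ``terms`` are value-table column names ("predictor@scale"); the
    coefficient table rows are ["(Intercept)"] + terms.
    """

    terms: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    loglik: float
    n: int
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.terms) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        n, k = self.n, self.k
        if n - k - 1 <= 0:
            return float("inf")
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def z_values(self) -> np.ndarray:
        return self.estimates / self.std_errors

    @property
    def p_values(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.z_values))

    @property
    def intercept(self) -> float:
        return float(self.estimates[0])

    def coefficient_table(self) -> pd.DataFrame:
        """Per-term estimates, Wald standard errors, z values and
        two-sided p-values (significance starred at p < 0.05)."""
        rows = ["(Intercept)"] + list(self.terms)
        df = pd.DataFrame(
            {
                "Estimate": self.estimates,
                "Std. error": self.std_errors,
                "z value": self.z_values,
                "Pr(>|z|)": self.p_values,
            },
            index=pd.Index(rows, name="term"),
        )
        df["significant"] = df["Pr(>|z|)"] < 0.05
        return df


def fit_logistic(
    design: pd.DataFrame,
    response: pd.Series | np.ndarray,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> FittedModel:
    """Maximum-likelihood logistic fit of ``response`` on the (already
    standardized) ``design`` columns plus an intercept.

    Standard errors come from the inverse observed information; the
    optimizer must reach gradient norm < 1e-8 or the fit errors out.
    Rank-deficient designs and complete separation raise.
    """
    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float) if len(design.columns) else np.empty((len(y), 0))
    n, p = X.shape
    if n <= p + 1:
        raise ModelError(f"n={n} rows cannot identify {p + 1} parameters")
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ModelError("rank-deficient design matrix")
    model = sm.Logit(y, Xc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-12)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e6:
        raise SeparationError("estimates diverged: likely complete separation")
    grad = model.score(params)
    if np.linalg.norm(grad) >= 1e-8 * max(1.0, n):
        # retry with BFGS polishing before giving up
        res = model.fit(disp=0, method="bfgs", maxiter=500, start_params=params)
        params = np.asarray(res.params, dtype=float)
        if np.linalg.norm(model.score(params)) >= 1e-6 * max(1.0, n):
            raise ModelError("optimizer failed to converge to gradient tolerance")
    return FittedModel(
        terms=tuple(design.columns),
        estimates=params,
        std_errors=np.asarray(res.bse, dtype=float),
        loglik=float(res.llf),
        n=n,
        standardization=dict(standardization or {}),
    )


@dataclass
class ModelRanking:
    """All candidate subsets ranked by AICc ascending."""

    models: list[FittedModel]
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    @property
    def delta_aicc(self) -> np.ndarray:
        best = self.models[0].aicc
        return np.array([m.aicc - best for m in self.models])

    @property
    def support_set(self) -> list[FittedModel]:
        """Models with substantial support (ΔAICc < 2)."""
        return [m for m, d in zip(self.models, self.delta_aicc) if d < 2.0]

    @property
    def best(self) -> FittedModel:
        return self.models[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "terms": [" + ".join(m.terms) if m.terms else "(intercept only)" for m in self.models],
                "k": [m.k for m in self.models],
                "loglik": [m.loglik for m in self.models],
                "AIC": [m.aic for m in self.models],
                "AICc": [m.aicc for m in self.models],
                "dAICc": self.delta_aicc,
            }
        )


MAX_EXHAUSTIVE = 20


def all_subsets(
    design: pd.DataFrame,
    response: pd.Series | np.ndarray,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> ModelRanking:
    """Fit every subset of the candidate columns (2^p models, including
    the intercept-only model) and rank by AICc.

    Ties break toward the smaller model, then lexicographic term names.
    Subsets whose fit fails (e.g. separation) are excluded and recorded.
    """
    cols = sorted(design.columns)
    p = len(cols)
    if p > MAX_EXHAUSTIVE:
        raise ModelError(
            f"{p} candidates gives 2^{p} subsets; reduce the candidate set "
            f"below {MAX_EXHAUSTIVE} before an exhaustive search"
        )
    fitted: list[FittedModel] = []
    failures: list[tuple[tuple[str, ...], str]] = []
    for r in range(p + 1):
        for subset in itertools.combinations(cols, r):
            try:
                fitted.append(
                    fit_logistic(design[list(subset)], response, standardization)
                )
            except ModelError as exc:
                failures.append((subset, str(exc)))
    if not fitted:
        raise ModelError("no subset could be fitted")
    fitted.sort(key=lambda m: (m.aicc, m.k, m.terms))
    return ModelRanking(models=fitted, failures=failures)


def predict_suitability(model: FittedModel, stack: ScaledPredictorStack) -> PredictorRaster:
    """Apply a fitted model across the smoothed predictor stack.

    Per pixel: eta = intercept + sum estimate * (smoothed − train mean) /
    train SD, output = invlogit(eta). Nodata propagates. Year-indexed
    predictors use their first layer (map prediction is single-epoch).
    """
    if not model.terms:
        raise ModelError("model has no predictor terms to map")
    ref = None
    eta = None
    for term, beta in zip(model.terms, model.estimates[1:]):
        name, scale = split_column_name(term)
        layer = stack.get(name, scale)[0]
        if ref is None:
            ref = layer
            eta = np.full(ref.grid.shape, model.intercept, dtype=float)
        if term not in model.standardization:
            raise ModelError(f"no standardization constants for term {term!r}")
        mu, sd = model.standardization[term]
        eta = eta + beta * (layer.grid - mu) / sd
    out = expit(eta)
    out[~np.isfinite(eta)] = np.nan
    return PredictorRaster(
        name="suitability", grid=out, pixel_size=ref.pixel_size, origin=ref.origin
    )
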