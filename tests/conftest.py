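import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from habscale.raster import PredictorRaster


def make_station_table(
    n: int,
    n_presences: int,
    n_surveys: int = 2,
    effort: int = 60,
    spacing: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A simple valid station table on a regular grid of coordinates,
    presences spread round-robin across surveys."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(n) % side) * spacing + 125.0
    ys = (np.arange(n) // side) * spacing + 125.0
    detected = np.zeros(n, dtype=int)
    detected[rng.choice(n, size=n_presences, replace=False)] = 1
    return pd.DataFrame(
        {
            "station_id": [f"st{i:05d}" for i in range(n)],
            "survey_id": [f"sv{i % n_surveys}" for i in range(n)],
            "x": xs,
            "y": ys,
            "year": 2015,
            "effort_days": effort,
            "detected": detected,
        }
    )


def flat_raster(value: float, shape=(8, 8), pixel_size: float = 250.0, name: str = "flat"):
    return PredictorRaster(
        name=name,
        grid=np.full(shape, value, dtype=float),
        pixel_size=pixel_size,
        origin=(0.0, shape[0] * pixel_size),
    )


# --- independent logistic-regression oracles -------------------------------


def logistic_nll(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli negative log-likelihood of intercept + X @ beta."""
    eta = params[0] + X @ params[1:]
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def fit_logistic_oracle(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Direct NLL minimization (Nelder-Mead polish over BFGS start);
    independent of the package's statsmodels route."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    p = X.shape[1]
    res = minimize(
        logistic_nll, np.zeros(p + 1), args=(X, np.asarray(y, float)), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    res2 = minimize(
        logistic_nll, res.x, args=(X, np.asarray(y, float)), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    best = res2 if res2.fun < res.fun else res
    return best.x, float(-best.fun)


def grid_search_logistic(x: np.ndarray, y: np.ndarray, lo=-6.0, hi=6.0) -> np.ndarray:
    """Coarse-to-fine likelihood grid search for a 2-parameter logistic fit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b0_lo, b0_hi, b1_lo, b1_hi = lo, hi, lo, hi
    best = None
    for _ in range(6):
        b0s = np.linspace(b0_lo, b0_hi, 61)
        b1s = np.linspace(b1_lo, b1_hi, 61)
        vals = np.array(
            [[logistic_nll(np.array([b0, b1]), x[:, None], y) for b1 in b1s] for b0 in b0s]
        )
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = np.array([b0s[i], b1s[j]])
        db0 = (b0_hi - b0_lo) / 60
        db1 = (b1_hi - b1_lo) / 60
        b0_lo, b0_hi = best[0] - 2 * db0, best[0] + 2 * db0
        b1_lo, b1_hi = best[1] - 2 * db1, best[1] + 2 * db1
    return best


def correlated_columns(corr: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Columns with *exact* sample correlation matrix ``corr``."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, corr.shape[0]))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    L = np.linalg.cholesky(corr)
    return q @ L.T


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
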