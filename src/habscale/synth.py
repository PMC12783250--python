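"""Synthetic landscapes, camera-trap surveys, and validation points.

A "virtual ecologist" generator: spatially autocorrelated predictor
fields, a known logistic habitat–suitability model acting on predictors
smoothed at known scales, clustered multi-survey camera deployments with
low detection prevalence, and opportunistic presence-only validation
points sampled proportional to suitability. Every generator is a pure
function of its configuration and seed, so downstream estimators can be
checked against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .raster import DEFAULT_SCALES, PredictorRaster, RasterError, ScaleSet, focal_smooth


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class LandscapeConfig:
    """Geometry and statistical structure of the synthetic landscape.

    Defaults are a 256x256 grid at 250 m/pixel (a 64 km square), which is
    large enough to express the 250 m - 16 km scale ladder while staying
    desk-scale.
    """

    grid_rows: int = 256
    grid_cols: int = 256
    pixel_size: float = 250.0
    n_predictors: int = 5
    correlation_lengths: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.n_predictors <= 0:
            raise ConfigError("n_predictors must be positive")
        if not self.correlation_lengths:
            # fine-grained fields (1.5 pixels): predictors vary near the native
            # product resolution, so multi-scale structure is induced by the
            # smoothing ladder and the analysis scale stays identifiable
            self.correlation_lengths = tuple([1.5 * self.pixel_size] * self.n_predictors)
        self.correlation_lengths = tuple(float(v) for v in self.correlation_lengths)
        if len(self.correlation_lengths) != self.n_predictors:
            raise ConfigError("need one correlation length per predictor")
        if any(v <= 0 for v in self.correlation_lengths):
            raise ConfigError("correlation lengths must be positive")

    def predictor_names(self) -> list[str]:
        return [f"pred{i:02d}" for i in range(self.n_predictors)]


@dataclass
class TrueModel:
    """The generative habitat model: a logistic response to predictors
    smoothed at known scales.

    suitability = invlogit(intercept + sum_j coef_j * z_j) where z_j is
    the standardized focal mean of active predictor j at its true scale.
    """

    active_predictors: tuple[str, ...]
    true_scales: tuple[float, ...]
    coefficients: tuple[float, ...]
    intercept: float = 0.0
    scale_set: ScaleSet = field(default_factory=ScaleSet)

    def __post_init__(self) -> None:
        if not (len(self.active_predictors) == len(self.true_scales) == len(self.coefficients)):
            raise ConfigError("active_predictors, true_scales, coefficients must align")
        for s in self.true_scales:
            if s not in self.scale_set:
                raise ConfigError(f"true scale {s} not in the supported scale set")


@dataclass
class SurveyConfig:
    """Clustered multi-survey camera deployment parameters."""

    n_surveys: int = 7
    stations_per_survey: int = 222
    survey_extent: float = 10000.0
    effort_days_range: tuple[int, int] = (60, 180)
    target_prevalence: float = 0.095
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surveys <= 0 or self.stations_per_survey <= 0:
            raise ConfigError("survey counts must be positive")
        lo, hi = self.effort_days_range
        if lo < 1 or hi < lo:
            raise ConfigError("effort_days_range must satisfy 1 <= min <= max")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ConfigError("target_prevalence must lie in (0, 1)")


def generate_random_field(config: LandscapeConfig, predictor_index: int) -> PredictorRaster:
    """A stationary, spatially autocorrelated Gaussian random field.

    Built by circular (FFT) convolution of white noise with a Gaussian
    kernel whose bandwidth is the predictor's correlation length, then
    standardized to zero mean and unit variance. Deterministic given
    (config.seed, predictor_index).
    """
    if predictor_index >= config.n_predictors:
        raise ConfigError("predictor_index out of range")
    rng = np.random.default_rng([config.seed, predictor_index])
    nr, nc = config.grid_rows, config.grid_cols
    white = rng.standard_normal((nr, nc))
    ell_px = config.correlation_lengths[predictor_index] / config.pixel_size
    if ell_px <= 0.55:
        # below pixel resolution: field is (almost) white noise
        grid = white
    else:
        fy = np.fft.fftfreq(nr)
        fx = np.fft.fftfreq(nc)
        # spectrum of a Gaussian kernel with sigma = ell_px
        ky, kx = np.meshgrid(fy, fx, indexing="ij")
        filt = np.exp(-2.0 * (np.pi * ell_px) ** 2 * (ky**2 + kx**2))
        grid = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
    grid = (grid - grid.mean()) / grid.std()
    return PredictorRaster(
        name=config.predictor_names()[predictor_index],
        grid=grid,
        pixel_size=config.pixel_size,
        origin=(0.0, nr * config.pixel_size),
    )


def generate_predictors(config: LandscapeConfig) -> list[PredictorRaster]:
    return [generate_random_field(config, i) for i in range(config.n_predictors)]


def compute_true_suitability(
    predictors: Sequence[PredictorRaster], model: TrueModel
) -> PredictorRaster:
    """Ground-truth suitability raster from the generative logistic model.

    Each active predictor is focal-mean smoothed at its true scale and
    standardized over valid cells before entering the linear predictor.
    """
    by_name = {r.name: r for r in predictors}
    missing = [p for p in model.active_predictors if p not in by_name]
    if missing:
        raise ConfigError(f"active predictors missing from the stack: {missing}")
    ref = predictors[0]
    eta = np.full(ref.grid.shape, model.intercept, dtype=float)
    for name, scale, coef in zip(model.active_predictors, model.true_scales, model.coefficients):
        sm = focal_smooth(by_name[name], scale).grid
        z = (sm - np.nanmean(sm)) / np.nanstd(sm)
        eta = eta + coef * z
    return PredictorRaster(
        name="true_suitability",
        grid=expit(eta),
        pixel_size=ref.pixel_size,
        origin=ref.origin,
    )


def _calibrate_detection_scaler(truth_at_stations: np.ndarray, target: float) -> float:
    """Bisection for the multiplicative detection scaler q such that
    mean(min(q * truth, 1)) matches the target prevalence."""
    t = np.asarray(truth_at_stations, dtype=float)
    if t.max() <= 0:
        return 0.0

    def realized(q: float) -> float:
        return float(np.minimum(q * t, 1.0).mean())

    lo, hi = 0.0, 1.0
    while realized(hi) < target and hi < 1e9:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_surveys(truth: PredictorRaster, cfg: SurveyConfig) -> pd.DataFrame:
    """Simulate clustered camera-trap surveys over a suitability surface.

    Stations fall in ``n_surveys`` circular clusters of radius
    ``survey_extent``; each gets a uniform operational-effort draw and a
    Bernoulli detection with probability q * truth at its pixel, q being
    a detection scaler calibrated so realized prevalence approximates
    ``target_prevalence``. Returns the station table (station_id,
    survey_id, x, y, year, effort_days, detected).
    """
    rng = np.random.default_rng([cfg.seed, 7102])
    xmin, ymin, xmax, ymax = truth.bounds
    width, height = xmax - xmin, ymax - ymin
    if cfg.survey_extent >= max(width, height):
        raise ConfigError("survey_extent exceeds the raster extent")
    records: list[dict] = []
    margin = min(cfg.survey_extent, 0.45 * min(width, height))
    for s in range(cfg.n_surveys):
        cx = rng.uniform(xmin + margin, xmax - margin)
        cy = rng.uniform(ymin + margin, ymax - margin)
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            raise ConfigError(f"survey cluster {s} falls outside the raster")
        placed = 0
        while placed < cfg.stations_per_survey:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = cfg.survey_extent * math.sqrt(rng.uniform())
            x, y = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
            if not (xmin <= x < xmax and ymin < y <= ymax):
                continue
            records.append(
                {
                    "station_id": f"S{s:02d}-{placed:04d}",
                    "survey_id": f"survey{s:02d}",
                    "x": x,
                    "y": y,
                    "year": int(rng.integers(2008, 2025)),
                    "effort_days": int(
                        rng.integers(cfg.effort_days_range[0], cfg.effort_days_range[1] + 1)
                    ),
                }
            )
            placed += 1
    df = pd.DataFrame.from_records(records)
    rows = np.empty(len(df), dtype=int)
    cols = np.empty(len(df), dtype=int)
    for i, (x, y) in enumerate(zip(df["x"], df["y"])):
        rows[i], cols[i] = truth.pixel_of(x, y)
    t = truth.grid[rows, cols]
    t = np.where(np.isfinite(t), t, 0.0)
    q = _calibrate_detection_scaler(t, cfg.target_prevalence)
    p = np.minimum(q * t, 1.0)
    df["detected"] = (rng.uniform(size=len(df)) < p).astype(int)
    return df


def simulate_validation_points(
    truth: PredictorRaster, n_points: int, seed: int
) -> pd.DataFrame:
    """Opportunistic presence-only points sampled proportional to suitability.

    Rejection sampling: a uniform location is accepted with probability
    truth / max(truth). Returns a DataFrame with columns (point_id, x, y).
    """
    if n_points < 1:
        raise ConfigError("n_points must be >= 1")
    vals = truth.grid[np.isfinite(truth.grid)]
    vmax = float(vals.max()) if vals.size else 0.0
    if vmax <= 0:
        raise RasterError("truth raster is all zero: no valid sampling density")
    rng = np.random.default_rng([seed, 9221])
    xmin, ymin, xmax, ymax = truth.bounds
    xs, ys = [], []
    while len(xs) < n_points:
        m = max(4 * (n_points - len(xs)), 64)
        x = rng.uniform(xmin, xmax, size=m)
        y = rng.uniform(ymin, ymax, size=m)
        u = rng.uniform(size=m)
        for xi, yi, ui in zip(x, y, u):
            r, c = truth.pixel_of(xi, yi)
            nr, nc = truth.shape
            if not (0 <= r < nr and 0 <= c < nc):
                continue
            t = truth.grid[r, c]
            if np.isfinite(t) and ui < t / vmax:
                xs.append(xi)
                ys.append(yi)
                if len(xs) == n_points:
                    break
    return pd.DataFrame(
        {"point_id": [f"V{i:04d}" for i in range(n_points)], "x": xs, "y": ys}
    )


def generate_zones(
    truth: PredictorRaster,
    n_blocks: int = 4,
    protected_fraction: float = 0.3,
    seed: int = 0,
) -> list[dict]:
    """Partition the landscape into an n_blocks x n_blocks grid of
    rectangular zones and flag a random subset as protected.

    Returns GeoJSON-style features (dicts) with properties ``name``,
    ``protected`` and ``landuse`` (unprotected zones cycle through the
    community land-use classes).
    """
    rng = np.random.default_rng([seed, 5517])
    xmin, ymin, xmax, ymax = truth.bounds
    dx = (xmax - xmin) / n_blocks
    dy = (ymax - ymin) / n_blocks
    n_zones = n_blocks * n_blocks
    n_prot = max(1, int(round(protected_fraction * n_zones)))
    prot_ids = set(rng.choice(n_zones, size=n_prot, replace=False).tolist())
    landuses = ["paddy", "oil-palm smallholding", "community mosaic"]
    feats = []
    for i in range(n_blocks):
        for j in range(n_blocks):
            k = i * n_blocks + j
            x0, y0 = xmin + j * dx, ymin + i * dy
            poly = [
                [x0, y0],
                [x0 + dx, y0],
                [x0 + dx, y0 + dy],
                [x0, y0 + dy],
                [x0, y0],
            ]
            protected = k in prot_ids
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [poly]},
                    "properties": {
                        "name": f"zone{k:02d}",
                        "protected": protected,
                        "landuse": None if protected else landuses[k % 3],
                    },
                }
            )
    return feats


def write_stations_csv(path: str | Path, stations: pd.DataFrame) -> None:
    cols = ["station_id", "survey_id", "x", "y", "year", "effort_days", "detected"]
    stations.loc[:, cols].to_csv(path, index=False)


def write_zones_geojson(path: str | Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
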