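"""Station-level filtering, balancing, and train/test partitioning.

The station table is a pandas DataFrame with columns (station_id,
survey_id, x, y, year, effort_days, detected). Detections of a rare
species produce strongly zero-inflated tables (prevalence < 0.1), which
logistic models handle poorly; the balancing step builds replicate
datasets with equal presences and absences, sampling absences survey by
survey so each replicate preserves the spatial footprint of the effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

STATION_COLUMNS = ["station_id", "survey_id", "x", "y", "year", "effort_days", "detected"]


class StationError(ValueError):
    pass


def validate_stations(stations: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STATION_COLUMNS if c not in stations.columns]
    if missing:
        raise StationError(f"station table missing columns: {missing}")
    if stations["station_id"].duplicated().any():
        raise StationError("station_id values must be unique")
    if not stations["detected"].isin([0, 1]).all():
        raise StationError("detected must be 0/1")
    if (stations["effort_days"] < 0).any():
        raise StationError("effort_days must be non-negative")
    return stations


def filter_min_effort(stations: pd.DataFrame, min_days: int = 30) -> pd.DataFrame:
    """Keep stations that operated for at least ``min_days`` days."""
    out = stations[stations["effort_days"] >= min_days].reset_index(drop=True)
    log.info("filter_min_effort: removed %d of %d stations", len(stations) - len(out), len(stations))
    return out


def dedupe_within_buffer(stations: pd.DataFrame, radius: float = 500.0) -> pd.DataFrame:
    """Drop stations strictly within ``radius`` meters of an already-kept one.

    Greedy single pass; presence stations are processed before absences
    (so detections of a rare species are preferentially retained), each
    class in station_id order.
    """
    if len(stations) == 0:
        return stations.reset_index(drop=True)
    ordered = stations.sort_values(
        ["detected", "station_id"], ascending=[False, True]
    ).reset_index(drop=True)
    coords = ordered[["x", "y"]].to_numpy(dtype=float)
    kept_idx: list[int] = []
    for i in range(len(ordered)):
        if kept_idx:
            d = np.hypot(*(coords[kept_idx] - coords[i]).T)
            if (d < radius).any():
                continue
        kept_idx.append(i)
    out = ordered.iloc[kept_idx]
    out = out.sort_values("station_id").reset_index(drop=True)
    log.info("dedupe_within_buffer: removed %d of %d stations", len(stations) - len(out), len(stations))
    return out


def drop_undetecting_surveys(stations: pd.DataFrame) -> pd.DataFrame:
    """Remove every station of surveys that recorded no detections at all."""
    sums = stations.groupby("survey_id")["detected"].sum()
    keep = sums[sums > 0].index
    if len(keep) == 0:
        raise StationError("every survey failed to detect: nothing to model")
    out = stations[stations["survey_id"].isin(keep)].reset_index(drop=True)
    log.info(
        "drop_undetecting_surveys: removed %d of %d stations (%d empty surveys)",
        len(stations) - len(out), len(stations), (sums == 0).sum(),
    )
    return out


def prevalence(stations: pd.DataFrame) -> float:
    """Fraction of stations with a detection."""
    if len(stations) == 0:
        raise StationError("empty station table")
    return float(stations["detected"].mean())


@dataclass
class BalancedDataset:
    """One balanced presence/absence replicate, optionally partitioned."""

    replicate_id: int
    rows: pd.DataFrame
    seed: int

    @property
    def n_presences(self) -> int:
        return int((self.rows["detected"] == 1).sum())

    @property
    def n_absences(self) -> int:
        return int((self.rows["detected"] == 0).sum())

    def train_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["split"] == "train"]

    def test_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["split"] == "test"]


def bootstrap_balanced(
    stations: pd.DataFrame, n_replicates: int = 10, seed: int = 0
) -> list[BalancedDataset]:
    """Build balanced replicate datasets.

    Every presence is kept in every replicate; per survey, absences are
    sampled to match that survey's presence count — without replacement
    when the survey holds enough absences, with replacement (logged)
    otherwise. Replicates differ only in the absence draw.
    """
    pres = stations[stations["detected"] == 1]
    surveys = stations["survey_id"].unique()
    pres_counts = pres.groupby("survey_id").size()
    for s in surveys:
        if pres_counts.get(s, 0) == 0:
            raise StationError(f"survey {s!r} has no presences; drop it before balancing")
        n_abs = int((stations["survey_id"] == s).sum() - pres_counts[s])
        if n_abs == 0:
            raise StationError(f"survey {s!r} has no absences to sample")
    out = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng([seed, rep])
        parts = [pres]
        for s in sorted(surveys):
            need = int(pres_counts[s])
            pool = stations[(stations["survey_id"] == s) & (stations["detected"] == 0)]
            if len(pool) >= need:
                idx = rng.choice(len(pool), size=need, replace=False)
            else:
                log.warning(
                    "survey %s: only %d absences for %d presences; sampling with replacement",
                    s, len(pool), need,
                )
                idx = rng.choice(len(pool), size=need, replace=True)
            parts.append(pool.iloc[idx])
        rows = pd.concat(parts, ignore_index=True)
        out.append(BalancedDataset(replicate_id=rep, rows=rows, seed=seed))
    return out


def partition_train_test(dataset: BalancedDataset, seed: int = 0) -> BalancedDataset:
    """Stratified 4:1 train/test split of a balanced dataset.

    Within each class the test count is the nearest integer to n/5
    (at least 1); the rest trains. Deterministic given the seed.
    """
    rows = dataset.rows.copy()
    rng = np.random.default_rng([seed, dataset.replicate_id, 41])
    split = np.empty(len(rows), dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(rows["detected"].to_numpy() == cls)
        n = len(idx)
        if n < 5:
            raise StationError(f"class {cls} has {n} rows; need at least 5 for a 4:1 split")
        n_test = max(1, int(round(n / 5)))
        perm = rng.permutation(n)
        split[idx[perm[:n_test]]] = "test"
        split[idx[perm[n_test:]]] = "train"
    rows["split"] = split
    return BalancedDataset(replicate_id=dataset.replicate_id, rows=rows, seed=dataset.seed)
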