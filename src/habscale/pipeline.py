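"""End-to-end orchestration of the habitat-suitability workflow.

Stages: synthesize (or ingest) → station filtering → focal smoothing and
extraction → balanced bootstrap replicates → per-replicate scale
optimization, pruning, exhaustive model selection and threshold
evaluation → best-replicate choice → suitability map → Boyce validation
→ gap analysis. One master seed spawns independent per-stage streams so
any stage can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, gaps, models, scales, stations, synth
from .raster import (
    DEFAULT_SCALES,
    ScaleSet,
    column_name,
    extract_at_stations,
    smooth_stack,
    write_ascii_grid,
    write_geotiff,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of the pipeline; the defaults are the analysis settings
    the workflow was designed around (30-day effort floor, 500 m dedupe
    buffer, |r| > 0.7 and VIF > 5 screens, ten balanced replicates, a
    30-threshold sweep, 4:1 train/test partition, 7-scale ladder)."""

    seed: int = 0
    scales: tuple[float, ...] = DEFAULT_SCALES
    min_effort_days: int = 30
    dedupe_radius_m: float = 500.0
    corr_threshold: float = 0.7
    vif_threshold: float = 5.0
    n_replicates: int = 10
    n_thresholds: int = 30
    boyce_window_width: float = 0.1
    boyce_n_windows: int = 101
    n_validation_points: int = 149

    # synthetic-landscape mode (used when station_csv is None)
    landscape: synth.LandscapeConfig = field(default_factory=synth.LandscapeConfig)
    true_model: synth.TrueModel = field(
        default_factory=lambda: synth.TrueModel(
            active_predictors=("pred00", "pred01", "pred02"),
            true_scales=(1000.0, 4000.0, 500.0),
            coefficients=(1.0, -0.8, 0.6),
            intercept=-2.9,
        )
    )
    survey: synth.SurveyConfig = field(default_factory=synth.SurveyConfig)
    zone_blocks: int = 4
    zone_protected_fraction: float = 0.3

    # file-input mode
    station_csv: str | None = None
    validation_csv: str | None = None
    zones_geojson: str | None = None
    raster_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("min_effort_days", "dedupe_radius_m", "corr_threshold",
                     "vif_threshold", "n_replicates", "n_thresholds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "landscape" in kwargs:
            kwargs["landscape"] = synth.LandscapeConfig(**kwargs["landscape"])
        if "true_model" in kwargs:
            tm = dict(kwargs["true_model"])
            for key in ("active_predictors", "true_scales", "coefficients"):
                if key in tm:
                    tm[key] = tuple(tm[key])
            kwargs["true_model"] = synth.TrueModel(**tm)
        if "survey" in kwargs:
            kwargs["survey"] = synth.SurveyConfig(**kwargs["survey"])
        if "scales" in kwargs:
            kwargs["scales"] = tuple(kwargs["scales"])
        return cls(**kwargs)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


@dataclass
class ReplicateResult:
    replicate_id: int
    scale_result: scales.ScaleSelectionResult
    candidates: scales.CandidateSet
    ranking: models.ModelRanking
    optimal: evaluation.ThresholdMetrics


def analyze_replicate(
    dataset: stations.BalancedDataset,
    values: pd.DataFrame,
    scale_set: ScaleSet,
    corr_threshold: float = 0.7,
    vif_threshold: float = 5.0,
    n_thresholds: int = 30,
) -> ReplicateResult:
    """Scale scan, pruning, exhaustive model selection and threshold
    evaluation for one balanced replicate (scan and fits on the train
    split; metrics on the test split)."""
    train = dataset.train_rows()
    test = dataset.test_rows()
    v_train = values.loc[train["station_id"]]
    v_test = values.loc[test["station_id"]]
    y_train = train["detected"].to_numpy()
    y_test = test["detected"].to_numpy()

    scale_result, candidates = scales.select_candidates(
        v_train, y_train, scale_set, corr_threshold, vif_threshold
    )
    cols = candidates.columns()
    z_train, consts = models.standardize(v_train[cols])
    ranking = models.all_subsets(z_train, y_train, consts)
    best = ranking.best
    # apply the training standardization to the test rows
    z_test = pd.DataFrame(
        {c: (v_test[c].to_numpy(dtype=float) - consts[c][0]) / consts[c][1] for c in best.terms},
        index=v_test.index,
    )
    from scipy.special import expit

    eta = best.intercept + (
        z_test.to_numpy() @ best.estimates[1:] if best.terms else 0.0
    )
    probs = expit(np.asarray(eta, dtype=float).reshape(-1) + np.zeros(len(v_test)))
    metrics = evaluation.sweep_thresholds(probs, y_test, n_thresholds)
    optimal = evaluation.select_optimal_threshold(metrics)
    return ReplicateResult(dataset.replicate_id, scale_result, candidates, ranking, optimal)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and write the artifact directory.

    Returns the run manifest (also written as manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.echo(), "seed": config.seed, "stages": [], "outputs": {}}

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise PipelineError(stage, str(exc)) from exc

    scale_set = ScaleSet(config.scales)

    # --- stage: inputs (synthesize or load) -------------------------------
    try:
        if config.station_csv is None:
            lconf = dataclasses.replace(
                config.landscape, seed=stage_seed(config.seed, "landscape")
            )
            predictors = synth.generate_predictors(lconf)
            truth = synth.compute_true_suitability(predictors, config.true_model)
            sconf = dataclasses.replace(config.survey, seed=stage_seed(config.seed, "survey"))
            station_table = synth.simulate_surveys(truth, sconf)
            validation = synth.simulate_validation_points(
                truth, config.n_validation_points, stage_seed(config.seed, "validation")
            )
            zone_feats = synth.generate_zones(
                truth,
                n_blocks=config.zone_blocks,
                protected_fraction=config.zone_protected_fraction,
                seed=stage_seed(config.seed, "zones"),
            )
            zones = gaps.load_zones(zone_feats)
            synth.write_stations_csv(outdir / "stations.csv", station_table)
            validation.to_csv(outdir / "validation_points.csv", index=False)
            synth.write_zones_geojson(outdir / "zones.geojson", zone_feats)
        else:
            from .raster import read_ascii_grid, read_geotiff

            station_table = stations.validate_stations(pd.read_csv(config.station_csv))
            validation = pd.read_csv(config.validation_csv)
            zones = gaps.load_zones(config.zones_geojson)
            predictors = []
            for name, path in config.raster_paths.items():
                reader = read_geotiff if str(path).endswith((".tif", ".tiff")) else read_ascii_grid
                predictors.append(reader(path, name=name))
            truth = None
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("inputs", exc)
    manifest["stages"].append("inputs")

    # --- stage: station filtering -----------------------------------------
    try:
        filtered = stations.filter_min_effort(station_table, config.min_effort_days)
        filtered = stations.dedupe_within_buffer(filtered, config.dedupe_radius_m)
        filtered = stations.drop_undetecting_surveys(filtered)
        prev = stations.prevalence(filtered)
        manifest["n_stations"] = int(len(filtered))
        manifest["n_presences"] = int(filtered["detected"].sum())
        manifest["prevalence"] = prev
    except Exception as exc:
        fail("filtering", exc)
    manifest["stages"].append("filtering")

    # --- stage: smoothing + extraction ------------------------------------
    try:
        stack = smooth_stack(predictors, scale_set)
        values = extract_at_stations(stack, filtered)
        n_missing = int(values.isna().any(axis=1).sum())
        if n_missing:
            log.info("extraction: dropping %d stations on nodata", n_missing)
            keep = values.dropna().index
            filtered = filtered[filtered["station_id"].isin(keep)].reset_index(drop=True)
            values = values.loc[keep]
        manifest["n_stations_extracted"] = int(len(values))
    except Exception as exc:
        fail("extraction", exc)
    manifest["stages"].append("extraction")

    # --- stage: balancing + per-replicate modelling -----------------------
    try:
        balanced = stations.bootstrap_balanced(
            filtered, config.n_replicates, stage_seed(config.seed, "balance")
        )
        balanced = [
            stations.partition_train_test(d, stage_seed(config.seed, "partition"))
            for d in balanced
        ]
        results = [
            analyze_replicate(
                d, values, scale_set,
                config.corr_threshold, config.vif_threshold, config.n_thresholds,
            )
            for d in balanced
        ]
    except Exception as exc:
        fail("modelling", exc)
    manifest["stages"].append("modelling")

    # --- stage: best-replicate selection ----------------------------------
    best_i = evaluation.select_best_replicate([r.optimal for r in results])
    best_rep = results[best_i]
    best_model = best_rep.ranking.best
    manifest["best_replicate"] = best_rep.replicate_id
    manifest["best_model_terms"] = list(best_model.terms)
    manifest["optimal_threshold"] = best_rep.optimal.threshold
    manifest["test_auc"] = best_rep.optimal.auc
    manifest["test_kappa"] = best_rep.optimal.kappa
    manifest["test_tss"] = best_rep.optimal.tss
    manifest["stages"].append("selection")

    # --- stage: artifacts (tables, maps, validation, gap analysis) --------
    try:
        best_rep.scale_result.to_frame().to_csv(outdir / "scale_selection.csv", index=False)
        for r in results:
            r.ranking.to_frame().to_csv(
                outdir / f"ranking_rep{r.replicate_id:02d}.csv", index=False
            )
        best_model.coefficient_table().to_csv(outdir / "coefficients.csv")
        pd.DataFrame(
            {
                "replicate": [r.replicate_id for r in results],
                "threshold": [r.optimal.threshold for r in results],
                "sensitivity": [r.optimal.sensitivity for r in results],
                "specificity": [r.optimal.specificity for r in results],
                "kappa": [r.optimal.kappa for r in results],
                "tss": [r.optimal.tss for r in results],
                "auc": [r.optimal.auc for r in results],
            }
        ).to_csv(outdir / "evaluation.csv", index=False)

        suitability = models.predict_suitability(best_model, stack)
        write_geotiff(outdir / "suitability.tif", suitability)
        write_ascii_grid(outdir / "suitability.asc", suitability)

        val_vals = []
        for x, y in zip(validation["x"], validation["y"]):
            r, c = suitability.pixel_of(float(x), float(y))
            nr, nc = suitability.shape
            val_vals.append(
                suitability.grid[r, c] if 0 <= r < nr and 0 <= c < nc else np.nan
            )
        background = suitability.grid[np.isfinite(suitability.grid)]
        boyce = evaluation.continuous_boyce(
            np.asarray(val_vals), background,
            config.boyce_window_width, config.boyce_n_windows,
        )
        manifest["boyce_index"] = boyce.index
        pd.DataFrame(
            {"midpoint": boyce.ratio_midpoints, "pe_ratio": boyce.ratio}
        ).to_csv(outdir / "boyce_curve.csv", index=False)

        classmap = gaps.bin_suitability(suitability)
        class_raster = dataclasses.replace(
            suitability, name="suitability_class",
            grid=np.where(classmap.classes > 0, classmap.classes, np.nan).astype(float),
        )
        write_geotiff(outdir / "suitability_class.tif", class_raster)
        gap_table = gaps.zonal_area(classmap, zones)
        gap_table.to_csv(outdir / "gap_zonal.csv", index=False)
        summary = gaps.protection_summary(classmap, zones)
        summary.to_csv(outdir / "protection_summary.csv", index=False)
        manifest["fraction_high_protected"] = float(
            summary.loc[summary["class_id"] == 4, "fraction_protected"].iloc[0]
        )
    except Exception as exc:
        fail("artifacts", exc)
    manifest["stages"].append("artifacts")

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
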