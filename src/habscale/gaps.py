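"""Suitability-class binning, zonal areas, and protection gap accounting.

The continuous suitability surface is cut into four equal-width classes
(Low: x < 0.25, Low-Med: 0.25 ≤ x < 0.5, Med-High: 0.5 ≤ x < 0.75,
High: 0.75 ≤ x ≤ 1; the top bin is closed so 1.0 is classified). Zonal
statistics rasterize each polygon by pixel-center containment and report
per-zone, per-class areas in km² together with the fraction of each
class that falls inside the protected network.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .raster import PredictorRaster

log = logging.getLogger(__name__)

CLASS_LABELS = {1: "Low", 2: "Low-Med", 3: "Med-High", 4: "High"}
BIN_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)


class GapError(ValueError):
    pass


@dataclass
class Zone:
    name: str
    geometry: BaseGeometry
    protected: bool = False
    landuse: str | None = None


def load_zones(source: str | Path | dict | list) -> list[Zone]:
    """Read zones from GeoJSON (path, FeatureCollection dict, or feature
    list). Properties used: name, protected, landuse."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = json.load(fh)
    feats = source["features"] if isinstance(source, dict) else source
    zones = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        zones.append(
            Zone(
                name=str(props.get("name", f"zone{i:02d}")),
                geometry=shapely_shape(f["geometry"]),
                protected=bool(props.get("protected", False)),
                landuse=props.get("landuse"),
            )
        )
    return zones


@dataclass
class SuitabilityClassMap:
    """Integer class raster: 1..4 for the four suitability bins, 0 nodata."""

    classes: np.ndarray
    pixel_size: float
    origin: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, ytop = self.origin
        nr, nc = self.classes.shape
        xs = x0 + (np.arange(nc) + 0.5) * self.pixel_size
        ys = ytop - (np.arange(nr) + 0.5) * self.pixel_size
        return xs, ys

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2


def bin_suitability(suitability: PredictorRaster, tol: float = 1e-9) -> SuitabilityClassMap:
    """Discretize a [0, 1] suitability raster into the four equal-width
    classes. Values outside [0, 1] beyond ``tol`` raise; tiny float
    overshoot is clipped. Nodata maps to class 0."""
    g = suitability.grid
    finite = np.isfinite(g)
    if finite.any():
        lo, hi = np.nanmin(g), np.nanmax(g)
        if lo < -tol or hi > 1.0 + tol:
            raise GapError(f"suitability values outside [0, 1]: range [{lo}, {hi}]")
    clipped = np.clip(g, 0.0, 1.0)
    cls = np.zeros(g.shape, dtype=int)
    cls[finite] = np.digitize(clipped[finite], BIN_EDGES[1:-1], right=False) + 1
    return SuitabilityClassMap(
        classes=cls, pixel_size=suitability.pixel_size, origin=suitability.origin
    )


def _zone_mask(classmap: SuitabilityClassMap, geom: BaseGeometry) -> np.ndarray:
    xs, ys = classmap.pixel_centers()
    X, Y = np.meshgrid(xs, ys)
    return shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(classmap.shape)


def zonal_area(classmap: SuitabilityClassMap, zones: list[Zone]) -> pd.DataFrame:
    """Per-zone, per-class area accounting (pixel-center containment).

    Returns one row per (zone, class) — classes absent from a zone get
    area 0 — with columns: zone, protected, landuse, class_id, class_label,
    area_km2, prop_of_zone, prop_of_class_protected. Per-zone proportions
    sum to 1 for every non-empty zone.
    """
    valid = classmap.classes > 0
    px_area = classmap.pixel_area_km2
    class_total = {c: float(np.sum(classmap.classes == c)) * px_area for c in CLASS_LABELS}
    prot_mask = np.zeros(classmap.shape, dtype=bool)
    for z in zones:
        if z.protected:
            prot_mask |= _zone_mask(classmap, z.geometry)
    prot_by_class = {
        c: float(np.sum(prot_mask & (classmap.classes == c))) * px_area for c in CLASS_LABELS
    }
    frac_protected = {
        c: (prot_by_class[c] / class_total[c]) if class_total[c] > 0 else float("nan")
        for c in CLASS_LABELS
    }
    rows = []
    for z in zones:
        mask = _zone_mask(classmap, z.geometry) & valid
        n_zone = int(mask.sum())
        if n_zone == 0:
            warnings.warn(f"zone {z.name!r} contains no valid raster cells", stacklevel=2)
        for c, label in CLASS_LABELS.items():
            n = int(np.sum(mask & (classmap.classes == c)))
            rows.append(
                {
                    "zone": z.name,
                    "protected": z.protected,
                    "landuse": z.landuse,
                    "class_id": c,
                    "class_label": label,
                    "area_km2": n * px_area,
                    "prop_of_zone": (n / n_zone) if n_zone else 0.0,
                    "prop_of_class_protected": frac_protected[c],
                }
            )
    return pd.DataFrame(rows)


def protection_summary(classmap: SuitabilityClassMap, zones: list[Zone]) -> pd.DataFrame:
    """Per-class protected/unprotected areas across the landscape.

    Columns: class_id, class_label, total_km2, protected_km2,
    unprotected_km2, fraction_protected (NaN for classes with zero
    area — never a spurious 0), prop_of_protected_network (class
    composition of the protected area).
    """
    px_area = classmap.pixel_area_km2
    prot_mask = np.zeros(classmap.shape, dtype=bool)
    for z in zones:
        if z.protected:
            prot_mask |= _zone_mask(classmap, z.geometry)
    network_total = float(np.sum(prot_mask & (classmap.classes > 0))) * px_area
    rows = []
    for c, label in CLASS_LABELS.items():
        in_class = classmap.classes == c
        total = float(in_class.sum()) * px_area
        prot = float(np.sum(in_class & prot_mask)) * px_area
        rows.append(
            {
                "class_id": c,
                "class_label": label,
                "total_km2": total,
                "protected_km2": prot,
                "unprotected_km2": total - prot,
                "fraction_protected": (prot / total) if total > 0 else float("nan"),
                "prop_of_protected_network": (prot / network_total)
                if network_total > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
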