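"""Raster containers, Gaussian focal smoothing, point extraction, and I/O.

Rasters live in a single projected, planar CRS with meter units. Grids are
row-major from the top-left corner; a point (x, y) falls in pixel
(row, col) under half-open intervals [x0 + col*px, x0 + (col+1)*px) and
(y_top - (row+1)*px, y_top - row*px].

Missing data is carried as NaN in memory and as an explicit nodata value
(default -9999) on disk. Files are written either as single-band float32
GeoTIFF (via tifffile, with ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags) or as ESRI ASCII grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

NODATA = -9999.0

#: Smoothing scales in meters used throughout the analysis.
DEFAULT_SCALES: tuple[float, ...] = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0)


class RasterError(ValueError):
    """Raised for invalid raster geometry or content."""


@dataclass
class ScaleSet:
    """An ordered ladder of smoothing scales (meters)."""

    scales: tuple[float, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        s = tuple(float(v) for v in self.scales)
        if len(s) == 0 or any(b <= a for a, b in zip(s, s[1:])):
            raise RasterError("scales must be strictly increasing and non-empty")
        self.scales = s

    def __iter__(self):
        return iter(self.scales)

    def __contains__(self, value: float) -> bool:
        return any(math.isclose(value, s) for s in self.scales)


@dataclass
class PredictorRaster:
    """A single-band environmental predictor on a regular grid.

    Parameters
    ----------
    name : str
        Predictor identifier.
    grid : ndarray
        2-D float array, NaN marks nodata.
    pixel_size : float
        Cell edge length in meters.
    origin : (float, float)
        Map coordinates (x, y) of the top-left *corner* of the grid.
    year : int, optional
        Acquisition year for time-indexed predictors.
    """

    name: str
    grid: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    year: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise RasterError(f"{self.name}: grid must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise RasterError(f"{self.name}: pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full extent."""
        x0, ytop = self.origin
        nr, nc = self.grid.shape
        return (x0, ytop - nr * self.pixel_size, x0 + nc * self.pixel_size, ytop)

    def same_geometry(self, other: "PredictorRaster") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and math.isclose(self.pixel_size, other.pixel_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the pixel containing (x, y); may be out of range."""
        x0, ytop = self.origin
        col = int(math.floor((x - x0) / self.pixel_size))
        row = int(math.floor((ytop - y) / self.pixel_size))
        # top edge belongs to row 0
        if y == ytop:
            row = 0
        return row, col

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) pixel-center coords."""
        x0, ytop = self.origin
        nr, nc = self.grid.shape
        xs = x0 + (np.arange(nc) + 0.5) * self.pixel_size
        ys = ytop - (np.arange(nr) + 0.5) * self.pixel_size
        return xs, ys


def gaussian_kernel(scale: float, pixel_size: float) -> np.ndarray:
    """Truncated Gaussian focal-mean weights for a given scale.

    The kernel has sigma = scale / 2 and is hard-truncated at radius =
    scale (distances measured between cell centers, in meters). Weights
    are normalized to sum to one.
    """
    if scale < pixel_size:
        raise RasterError(
            f"scale {scale} m is below the pixel size {pixel_size} m; "
            "the kernel degenerates to a point"
        )
    r = int(math.ceil(scale / pixel_size))
    offs = np.arange(-r, r + 1, dtype=float)
    dx, dy = np.meshgrid(offs, offs)
    dist2 = (dx * dx + dy * dy) * pixel_size * pixel_size
    sigma = scale / 2.0
    w = np.exp(-dist2 / (2.0 * sigma * sigma))
    w[np.sqrt(dist2) > scale] = 0.0
    return w / w.sum()


def focal_smooth(raster: PredictorRaster, scale: float) -> PredictorRaster:
    """Gaussian focal mean of a raster at the given scale.

    Nodata cells do not contribute; weights are renormalized over the
    valid cells inside the window (the same rule handles grid edges, so
    no values are invented outside the extent). Nodata cells stay nodata.
    """
    valid = np.isfinite(raster.grid)
    if not valid.any():
        raise RasterError(f"{raster.name}: all-nodata raster cannot be smoothed")
    kernel = gaussian_kernel(scale, raster.pixel_size)
    filled = np.where(valid, raster.grid, 0.0)
    num = fftconvolve(filled, kernel, mode="same")
    den = fftconvolve(valid.astype(float), kernel, mode="same")
    out = np.full(raster.grid.shape, np.nan)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return replace(raster, grid=out)


@dataclass
class ScaledPredictorStack:
    """Focal-smoothed predictor layers keyed by (predictor name, scale).

    Each key maps to a list of layers; multiple entries per key represent
    year-indexed versions of the same predictor.
    """

    entries: dict[tuple[str, float], list[PredictorRaster]] = field(default_factory=dict)

    def add(self, name: str, scale: float, layer: PredictorRaster) -> None:
        self.entries.setdefault((name, float(scale)), []).append(layer)

    def get(self, name: str, scale: float) -> list[PredictorRaster]:
        key = (name, float(scale))
        if key not in self.entries:
            raise KeyError(f"no layer for predictor {name!r} at scale {scale}")
        return self.entries[key]

    @property
    def predictors(self) -> list[str]:
        return sorted({k[0] for k in self.entries})

    @property
    def scales(self) -> list[float]:
        return sorted({k[1] for k in self.entries})


def smooth_stack(
    predictors: Iterable[PredictorRaster], scales: ScaleSet | Sequence[float] = DEFAULT_SCALES
) -> ScaledPredictorStack:
    """Smooth every predictor at every scale of the ladder."""
    scales = ScaleSet(tuple(scales)) if not isinstance(scales, ScaleSet) else scales
    stack = ScaledPredictorStack()
    for rast in predictors:
        for s in scales:
            stack.add(rast.name, s, focal_smooth(rast, s))
    return stack


def column_name(predictor: str, scale: float) -> str:
    """Canonical value-table column name for a (predictor, scale) pair."""
    return f"{predictor}@{scale:g}"


def split_column_name(col: str) -> tuple[str, float]:
    name, _, scale = col.rpartition("@")
    return name, float(scale)


def _pick_year_layer(layers: list[PredictorRaster], year: int | None) -> PredictorRaster:
    """Layer whose year matches `year`; nearest year otherwise, ties to the
    earlier year. Un-yeared single layers match everything."""
    if len(layers) == 1 or year is None:
        return layers[0]
    years = [lyr.year if lyr.year is not None else year for lyr in layers]
    best = min(range(len(layers)), key=lambda i: (abs(years[i] - year), years[i]))
    return layers[best]


def extract_at_stations(stack: ScaledPredictorStack, stations: pd.DataFrame) -> pd.DataFrame:
    """Extract smoothed values at station locations.

    Returns one row per station (indexed by station_id) and one column per
    (predictor, scale). The value comes from the single pixel containing
    the station. Year-indexed predictors use the layer matching the
    station's year (nearest year otherwise, ties toward the earlier year).
    Stations falling on nodata yield NaN, to be dropped and logged by the
    caller; stations outside the raster extent raise an error.
    """
    keys = sorted(stack.entries)
    out = pd.DataFrame(index=pd.Index(stations["station_id"], name="station_id"))
    offenders: list[str] = []
    first_layers = [layers[0] for layers in stack.entries.values()]
    ref = first_layers[0]
    rows = np.empty(len(stations), dtype=int)
    cols = np.empty(len(stations), dtype=int)
    for i, (x, y) in enumerate(zip(stations["x"], stations["y"])):
        r, c = ref.pixel_of(float(x), float(y))
        rows[i], cols[i] = r, c
        nr, nc = ref.shape
        if not (0 <= r < nr and 0 <= c < nc):
            offenders.append(str(stations["station_id"].iloc[i]))
    if offenders:
        raise RasterError(f"stations outside raster extent: {', '.join(offenders)}")
    years = stations["year"] if "year" in stations.columns else pd.Series([None] * len(stations))
    for name, scale in keys:
        layers = stack.entries[(name, scale)]
        vals = np.empty(len(stations))
        if len(layers) == 1:
            vals = layers[0].grid[rows, cols]
        else:
            for i, yr in enumerate(years):
                lyr = _pick_year_layer(layers, None if pd.isna(yr) else int(yr))
                vals[i] = lyr.grid[rows[i], cols[i]]
        out[column_name(name, scale)] = vals
    return out


# ---------------------------------------------------------------------------
# I/O


def write_geotiff(path: str | Path, raster: PredictorRaster, nodata: float = NODATA) -> None:
    """Write a single-band float32 GeoTIFF with georeferencing tags."""
    import tifffile

    grid = np.where(np.isfinite(raster.grid), raster.grid, nodata).astype(np.float32)
    x0, ytop = raster.origin
    px = raster.pixel_size
    extratags = [
        (33550, "d", 3, (px, px, 0.0)),  # ModelPixelScaleTag
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, ytop, 0.0)),  # ModelTiepointTag
        (42113, "s", 0, str(nodata)),  # GDAL_NODATA
    ]
    tifffile.imwrite(str(path), grid, extratags=extratags)


def read_geotiff(path: str | Path, name: str | None = None, year: int | None = None) -> PredictorRaster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        grid = page.asarray().astype(float)
        tags = page.tags
        px = 1.0
        origin = (0.0, 0.0)
        nodata = NODATA
        if 33550 in tags:
            px = float(tags[33550].value[0])
        if 33922 in tags:
            tp = tags[33922].value
            origin = (float(tp[3]), float(tp[4]))
        if 42113 in tags:
            nodata = float(tags[42113].value)
    grid[grid == nodata] = np.nan
    return PredictorRaster(
        name=name or Path(path).stem, grid=grid, pixel_size=px, origin=origin, year=year
    )


def write_ascii_grid(path: str | Path, raster: PredictorRaster, nodata: float = NODATA) -> None:
    """Write an ESRI ASCII grid (plain-text raster interchange format)."""
    nr, nc = raster.grid.shape
    x0, ytop = raster.origin
    yll = ytop - nr * raster.pixel_size
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {x0:.6f}\nyllcorner {yll:.6f}\n"
        f"cellsize {raster.pixel_size:.6f}\nNODATA_value {nodata:g}\n"
    )
    body = np.where(np.isfinite(raster.grid), raster.grid, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str | Path, name: str | None = None, year: int | None = None) -> PredictorRaster:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    nodata = hdr.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    px = hdr["cellsize"]
    ytop = hdr["yllcorner"] + hdr["nrows"] * px
    return PredictorRaster(
        name=name or Path(path).stem,
        grid=grid,
        pixel_size=px,
        origin=(hdr["xllcorner"], ytop),
        year=year,
    )
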