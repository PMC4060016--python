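"""File I/O: single-band GeoTIFF rasters, occurrence/plot CSVs, config files.

Rasters are stored as single-band float32 GeoTIFFs with georeferencing in the
standard ModelPixelScale / ModelTiepoint tags and the nodata value in the
GDAL_NODATA tag, so outputs open in QGIS/GDAL. Reading and writing round-trip
values, grid geometry and the nodata mask bit-exactly for float32 data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grid import Grid, RasterLayer

log = logging.getLogger("stepwise_impact")

__all__ = [
    "read_raster",
    "write_raster",
    "read_occurrences",
    "read_plot_table",
    "load_config",
    "OccurrenceSet",
    "FormatError",
    "EmptyInputError",
]

NODATA_VALUE = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class FormatError(ValueError):
    """Input file does not match the expected format."""


class EmptyInputError(ValueError):
    """Input file contained no usable records."""


class OccurrenceSet:
    """Georeferenced presence points in projected coordinates."""

    def __init__(self, points: np.ndarray, source_labels: list[str] | None = None):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x,y coordinates")
        if np.isnan(points).any():
            raise ValueError("occurrence coordinates must not contain NaN")
        self.points = points
        self.source_labels = source_labels

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def cells(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cell containing each point."""
        return grid.point_to_cell(self.x, self.y)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y}).to_csv(path, index=False)


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write a RasterLayer as a single-band float32 GeoTIFF."""
    values = layer.values.astype(np.float32)
    values = values.copy()
    values[layer.nodata_mask] = NODATA_VALUE
    g = layer.grid
    desc = json.dumps(
        {"name": layer.name, "units": layer.units, "crs": g.crs_label}
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin[0], g.origin[1], 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(NODATA_VALUE), True),
    ]
    tifffile.imwrite(
        str(path),
        values,
        photometric="minisblack",
        description=desc,
        extratags=extratags,
    )


def read_raster(path: str | Path) -> RasterLayer:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or similar)."""
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        if len(series.shape) != 2:
            raise FormatError(
                f"{path}: expected a single-band raster, got shape {series.shape}"
            )
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        tags = page.tags

        cell_size = 1.0
        if _TAG_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            if abs(sx - sy) > 1e-9 * max(abs(sx), 1.0):
                raise FormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
            cell_size = float(sx)
        origin = (0.0, 0.0)
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            # tie point maps raster (i, j) to model (x, y); we require i=j=0
            origin = (float(tp[3]) - float(tp[0]) * cell_size, float(tp[4]) + float(tp[1]) * cell_size)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)

        name, units, crs = "", "", "local-metres"
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                name = meta.get("name", "")
                units = meta.get("units", "")
                crs = meta.get("crs", crs)
            except (json.JSONDecodeError, TypeError):
                pass

    grid = Grid(values.shape[0], values.shape[1], cell_size=cell_size, origin=origin, crs_label=crs)
    if nodata is None:
        mask = ~np.isfinite(values)
    else:
        mask = (values == nodata) | ~np.isfinite(values)
    values = values.copy()
    values[mask] = 0.0
    return RasterLayer(grid=grid, values=values, nodata_mask=mask, name=name, units=units)


def read_occurrences(path: str | Path, grid: Grid) -> OccurrenceSet:
    """Read occurrence points from a CSV with columns ``x,y``.

    Points outside the grid extent and malformed rows are dropped (and the
    drop count logged); zero surviving points is an error.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path}: occurrence CSV must have columns x,y (got {list(df.columns)})")
    x = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    inside = np.zeros_like(finite)
    inside[finite] = grid.contains(x[finite], y[finite])
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("read_occurrences: dropped %d of %d points (outside extent or malformed)",
                 n_dropped, len(df))
    if not inside.any():
        raise EmptyInputError(f"{path}: no valid in-extent occurrence points")
    return OccurrenceSet(np.column_stack([x[inside], y[inside]]))


def read_plot_table(path: str | Path) -> pd.DataFrame:
    """Read a plot-survey CSV with columns ``class,plot_id,nests``."""
    df = pd.read_csv(path)
    required = {"class", "plot_id", "nests"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: plot CSV must have columns {sorted(required)}")
    df["nests"] = pd.to_numeric(df["nests"], errors="raise").astype(int)
    if (df["nests"] < 0).any():
        raise ValueError(f"{path}: negative nest counts")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
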