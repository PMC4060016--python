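"""Georeferenced grid and raster layer primitives.

All stages of the pipeline exchange :class:`RasterLayer` objects. A layer is a
2-D float array on a :class:`Grid` (projected metres, cell-centre
registration, row 0 = north) plus a boolean nodata mask. Cross-layer
operations require identical grids ("alignment"); nodata propagates through
every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "RasterLayer", "AlignmentError"]


class AlignmentError(ValueError):
    """Raised when an operation mixes layers on different grids."""


@dataclass(frozen=True)
class Grid:
    """Regular raster grid in projected coordinates.

    Parameters
    ----------
    n_rows, n_cols:
        Raster shape; both must be >= 1.
    cell_size:
        Cell edge length in metres. The default 500 m gives 25 ha cells.
    origin:
        (x, y) projected coordinates of the *upper-left corner* of the
        upper-left cell. Row index increases southward.
    crs_label:
        Opaque coordinate-system label carried through I/O.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 500.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local-metres"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares (cell_size^2 / 10,000; 500 m => 25 ha)."""
        return self.cell_size**2 / 1e4

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        x0, y0 = self.origin
        return (x0, y0 - self.n_rows * self.cell_size, x0 + self.n_cols * self.cell_size, y0)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of cell-centre coordinates, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = y0 - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def point_to_cell(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map projected coordinates to (row, col) indices (no bounds check)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)


@dataclass
class RasterLayer:
    """A single-band raster: values on a Grid plus a nodata mask."""

    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata_mask shape does not match grid")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError(f"layer {self.name!r} has non-finite values outside nodata")

    def aligned_with(self, other: "RasterLayer") -> bool:
        return self.grid == other.grid

    def require_aligned(self, other: "RasterLayer") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"layers {self.name!r} and {other.name!r} are on different grids"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def masked(self, fill: float = np.nan) -> np.ndarray:
        """Values with nodata cells replaced by `fill`."""
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out

    def copy_with(self, values: np.ndarray, name: str | None = None, units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            grid=self.grid,
            values=values,
            nodata_mask=self.nodata_mask.copy(),
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )


def require_aligned(*layers: RasterLayer) -> None:
    """Raise AlignmentError unless every layer shares the first one's grid."""
    for other in layers[1:]:
        layers[0].require_aligned(other)
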