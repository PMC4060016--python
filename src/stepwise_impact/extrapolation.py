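"""National extrapolation of nests from class areas × occupancy × density.

Class areas are counted over the suitable portion of the land-cover raster
(25 ha per 500 m cell). Row arithmetic truncates toward zero before summing:
occupied_ha = ⌊A·ψ⌋ and total_nests = ⌊A·ψ·D⌋ — the convention under which
per-class report values and their totals are mutually consistent. The
continuous (unfloored) values are carried in extra columns for downstream
raster work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityEstimate
from .grid import RasterLayer, require_aligned
from .landcover import ID_TO_CLASS

__all__ = ["ExtrapolationRow", "ExtrapolationTable", "class_area", "extrapolate"]


@dataclass(frozen=True)
class ExtrapolationRow:
    land_cover_class: str
    potential_ha: float
    n_plots: int
    n_nests: int
    occupancy: float
    density: int
    occupied_ha: int
    total_nests: int
    occupied_ha_exact: float
    total_nests_exact: float


@dataclass
class ExtrapolationTable:
    rows: list[ExtrapolationRow]

    @property
    def total_potential_ha(self) -> float:
        return sum(r.potential_ha for r in self.rows)

    @property
    def total_occupied_ha(self) -> int:
        return sum(r.occupied_ha for r in self.rows)

    @property
    def total_nests(self) -> int:
        return sum(r.total_nests for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([
            {"class": r.land_cover_class, "potential_ha": r.potential_ha,
             "n_plots": r.n_plots, "n_nests": r.n_nests, "occupancy": r.occupancy,
             "occupied_ha": r.occupied_ha, "density": r.density,
             "total_nests": r.total_nests,
             "occupied_ha_exact": r.occupied_ha_exact,
             "total_nests_exact": r.total_nests_exact}
            for r in self.rows
        ])
        total = pd.DataFrame([{
            "class": "TOTAL", "potential_ha": self.total_potential_ha,
            "n_plots": int(df["n_plots"].sum()), "n_nests": int(df["n_nests"].sum()),
            "occupancy": np.nan, "occupied_ha": self.total_occupied_ha,
            "density": np.nan, "total_nests": self.total_nests,
            "occupied_ha_exact": float(df["occupied_ha_exact"].sum()),
            "total_nests_exact": float(df["total_nests_exact"].sum()),
        }])
        return pd.concat([df, total], ignore_index=True)


def class_area(landcover: RasterLayer, mask: RasterLayer,
               cell_area_ha: float | None = None) -> dict[str, float]:
    """Hectares of each land-cover class inside the suitable mask."""
    require_aligned(landcover, mask)
    if cell_area_ha is None:
        cell_area_ha = landcover.grid.cell_area_ha
    sel = (mask.values > 0) & mask.valid & landcover.valid
    codes = landcover.values[sel].astype(int)
    out: dict[str, float] = {}
    for code, count in zip(*np.unique(codes, return_counts=True)):
        cls = ID_TO_CLASS.get(int(code), str(int(code)))
        out[cls] = float(count) * cell_area_ha
    return out


def extrapolate(areas: dict[str, float],
                estimates: list[DensityEstimate]) -> ExtrapolationTable:
    """Combine per-class suitable areas with density/occupancy estimates.

    Every class with positive area must have an estimate unless it is
    categorized unsuitable (those default to zero and are logged).
    """
    import logging

    log = logging.getLogger("stepwise_impact")
    by_class = {e.land_cover_class: e for e in estimates}
    from .landcover import DEFAULT_CATEGORIES

    rows = []
    for cls, area in areas.items():
        est = by_class.get(cls)
        if est is None:
            if DEFAULT_CATEGORIES.get(cls, "unsuitable") != "unsuitable":
                raise ValueError(f"no density estimate for class {cls!r} with area {area} ha")
            log.info("extrapolate: class %r treated as unsuitable (no estimate)", cls)
            est = DensityEstimate(cls, 0, 0, 0, 0.0, "unsuitable")
        occ_exact = area * est.occupancy
        nests_exact = area * est.occupancy * est.density
        rows.append(ExtrapolationRow(
            land_cover_class=cls, potential_ha=area,
            n_plots=est.n_plots, n_nests=est.n_nests,
            occupancy=est.occupancy, density=est.density,
            occupied_ha=math.floor(occ_exact + 1e-9),
            total_nests=math.floor(nests_exact + 1e-9),
            occupied_ha_exact=occ_exact, total_nests_exact=nests_exact,
        ))
    # estimates for classes with zero suitable area are legitimate; skip them
    return ExtrapolationTable(rows=rows)
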