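"""Foraging intensity and the per-pixel prey-consumption (impact) surface.

The foraging success rate F (prey per nest per hour) is the product of three
observed components measured at nest entrances: the forager return ("traffic")
rate r per minute, the fraction m of returns carrying material, and the
fraction q of material that is prey — F = 60·r·m·q. Seasonal foraging time is
the count of bright-sunshine hours (radiation ≥ 0.432 MJ m⁻² h⁻¹, the WMO
120 W m⁻² definition) over February–April, since paper wasps forage neither
at night nor in rain. Impact per cell = nests per cell × F × foraging hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .density import DensityEstimate
from .extrapolation import ExtrapolationTable
from .grid import RasterLayer, require_aligned
from .landcover import ID_TO_CLASS
from .synthetic import BRIGHT_THRESHOLD_MJ, SunshineStack

log = logging.getLogger("stepwise_impact")

__all__ = [
    "ForagingParams",
    "SeasonalHours",
    "ImpactRaster",
    "foraging_success_rate",
    "component_means",
    "seasonal_foraging_hours",
    "impact_surface",
    "national_totals",
]


def foraging_success_rate(traffic_rate: float, prop_material: float, prop_prey: float) -> float:
    """Prey captured per nest per hour: 60 · r · m · q (unrounded)."""
    for name, v in (("traffic_rate", traffic_rate), ("prop_material", prop_material),
                    ("prop_prey", prop_prey)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative")
    if prop_material > 1 or prop_prey > 1:
        raise ValueError("proportions must be <= 1")
    return 60.0 * traffic_rate * prop_material * prop_prey


def component_means(observations: list[float], exclusions: list[float] | None = None
                    ) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean and (min, max) range of per-site component values,
    after dropping listed outliers (exclusions are logged)."""
    excl = list(exclusions or [])
    kept = [v for v in observations if v not in excl]
    if excl:
        log.info("component_means: excluded %d outlier value(s): %s",
                 len(observations) - len(kept), excl)
    if not kept:
        raise ValueError("all observations excluded")
    return float(np.mean(kept)), (float(min(kept)), float(max(kept)))


@dataclass
class ForagingParams:
    """Observed foraging components and the derived success rate."""

    traffic_rate: float = 0.33      # returns per minute (range 0.23-0.46)
    prop_material: float = 0.30     # fraction of returns carrying material (0.25-0.38)
    prop_prey: float = 0.75         # fraction of material that is prey (0.70-0.80)

    @property
    def success_rate(self) -> float:
        return foraging_success_rate(self.traffic_rate, self.prop_material, self.prop_prey)


@dataclass
class SeasonalHours:
    layer: RasterLayer
    bright_threshold: float


def seasonal_foraging_hours(sunshine: SunshineStack,
                            bright_threshold: float = BRIGHT_THRESHOLD_MJ) -> SeasonalHours:
    """Per-cell count of bright hours (radiation ≥ threshold, closed bound)
    over the season covered by the stack."""
    counts = (sunshine.radiation >= bright_threshold).sum(axis=0).astype(float)
    layer = RasterLayer(grid=sunshine.grid, values=counts, name="foraging_hours", units="h")
    return SeasonalHours(layer=layer, bright_threshold=bright_threshold)


@dataclass
class ImpactRaster:
    layer: RasterLayer            # prey consumed per cell per season
    nests: RasterLayer            # expected nests per cell
    hours: RasterLayer
    success_rate: float

    @property
    def total_prey(self) -> float:
        return float(self.layer.values[self.layer.valid].sum())


def impact_surface(mask: RasterLayer, landcover: RasterLayer,
                   estimates: list[DensityEstimate], success_rate: float,
                   hours: SeasonalHours, cell_area_ha: float | None = None,
                   suitability: RasterLayer | None = None) -> ImpactRaster:
    """Per-pixel expected prey consumed per season.

    nests(cell) = cell_area_ha · ψ_c · D_c inside the suitable mask, else 0
    (unrounded — flooring is a table-report convention only);
    prey(cell) = nests · F · hours. Passing a continuous ``suitability``
    layer weights nests by suitability instead of the binary mask
    (sensitivity-analysis mode).
    """
    require_aligned(mask, landcover, hours.layer)
    if success_rate < 0:
        raise ValueError("success rate must be >= 0")
    grid = mask.grid
    if cell_area_ha is None:
        cell_area_ha = grid.cell_area_ha
    by_class = {e.land_cover_class: e for e in estimates}

    nests = np.zeros(grid.shape)
    codes = landcover.values.astype(int)
    missing: set[str] = set()
    for code in np.unique(codes):
        cls = ID_TO_CLASS.get(int(code), str(int(code)))
        est = by_class.get(cls)
        if est is None:
            missing.add(cls)
            continue
        sel = codes == code
        nests[sel] = cell_area_ha * est.occupancy * est.density
    for cls in sorted(missing):
        log.info("impact_surface: class %r has no estimate; treated as 0", cls)

    if suitability is not None:
        require_aligned(mask, suitability)
        weight = np.clip(suitability.values, 0.0, 1.0)
    else:
        weight = (mask.values > 0).astype(float)
    nests *= weight
    nodata = mask.nodata_mask | landcover.nodata_mask | hours.layer.nodata_mask
    nests[nodata] = 0.0
    prey = nests * success_rate * hours.layer.values
    prey[nodata] = 0.0
    return ImpactRaster(
        layer=RasterLayer(grid=grid, values=prey, nodata_mask=nodata,
                          name="impact", units="prey per cell per season"),
        nests=RasterLayer(grid=grid, values=nests, nodata_mask=nodata,
                          name="nests", units="nests per cell"),
        hours=hours.layer,
        success_rate=success_rate,
    )


def national_totals(impact: ImpactRaster, table: ExtrapolationTable,
                    success_rate: float, mean_hours: float,
                    hours_range: tuple[float, float] | None = None) -> dict:
    """Report the national prey budget two ways: summed over the impact
    raster, and from the extrapolation table (total nests × F × mean hours)."""
    raster_total = impact.total_prey
    table_total = table.total_nests * success_rate * mean_hours
    report = {
        "success_rate_prey_per_nest_hour": success_rate,
        "mean_seasonal_foraging_hours": mean_hours,
        "total_nests_table": table.total_nests,
        "prey_total_raster": raster_total,
        "prey_total_raster_billions": raster_total / 1e9,
        "prey_total_table": table_total,
        "prey_total_table_billions": table_total / 1e9,
    }
    if hours_range is not None:
        lo, hi = hours_range
        report["prey_total_table_low"] = table.total_nests * success_rate * lo
        report["prey_total_table_high"] = table.total_nests * success_rate * hi
    return report
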