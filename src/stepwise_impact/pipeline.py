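"""Stage-wise pipeline driver: simulate → sdm → density → extrapolate → impact.

Each stage reads its inputs from (and writes its artifacts into) one output
directory, so stages can be run individually or end-to-end. All randomness
derives from the single master seed via fixed per-stage offsets; identical
config + seed reproduces bit-identical table outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import density as density_mod
from . import extrapolation as extrap_mod
from . import foraging as foraging_mod
from . import sdm as sdm_mod
from . import synthetic as synth_mod
from .grid import Grid, RasterLayer
from .io import read_occurrences, read_plot_table, read_raster, write_raster
from .landcover import DEFAULT_CATEGORIES
from .synthetic import ENV_VARIABLES, EnvStack

log = logging.getLogger("stepwise_impact")

__all__ = ["run_pipeline", "run_stage", "DependencyError", "STAGES", "default_config"]

STAGES = ("simulate", "sdm", "density", "extrapolate", "impact", "report")


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


def default_config() -> dict:
    """Demo configuration: 100×100 synthetic landscape at field-study scales
    (253 occurrences; 114/93/206/53 plots in HSV/BUA/SAS/forest)."""
    return {
        "grid": {"n_rows": 100, "n_cols": 100, "cell_size": 500.0},
        "seed": 0,
        "simulate": {
            "smoothness": 6.0,
            "n_occurrences": 253,
            "bias_centres": [],
            "landcover_weights": {
                "WAT": 0.20, "HSV": 0.05, "BUA": 0.10, "SAS": 0.25,
                "OVP": 0.05, "HFV": 0.03, "TTG": 0.02, "FOR": 0.30,
            },
            "patchiness": 4.0,
            "plots": {"HSV": 114, "BUA": 93, "SAS": 206, "FOR": 53},
            "sunshine": {"season_days": 89, "hours_per_day": 12},
        },
        "sdm": {
            "n_runs": 50, "train_fraction": 0.75, "reg_lambda": 0.01,
            "background_size": 10000, "bandwidth": None, "importance": False,
        },
        "density": {"kw_classes": ["HSV", "BUA", "SAS"]},
        "extrapolate": {},
        "impact": {"bright_threshold": synth_mod.BRIGHT_THRESHOLD_MJ},
        "foraging": {"traffic_rate": 0.33, "prop_material": 0.30, "prop_prey": 0.75},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def _grid_from_config(cfg: dict) -> Grid:
    g = cfg["grid"]
    return Grid(int(g["n_rows"]), int(g["n_cols"]), float(g.get("cell_size", 500.0)),
                tuple(g.get("origin", (0.0, 0.0))))


def _require(out_dir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (out_dir / name).exists():
            raise DependencyError(
                f"stage {stage!r} requires artifact {name!r} in {out_dir}; "
                "run the upstream stage first")


def _read_env_stack(out_dir: Path, stage: str) -> EnvStack:
    _require(out_dir, stage, *[f"env_{v}.tif" for v in ENV_VARIABLES])
    return EnvStack({v: read_raster(out_dir / f"env_{v}.tif") for v in ENV_VARIABLES})


# --------------------------------------------------------------------------- stages

def stage_simulate(cfg: dict, out_dir: Path, seed: int) -> None:
    sc = cfg["simulate"]
    grid = _grid_from_config(cfg)
    env = synth_mod.generate_env_stack(grid, seed=seed, smoothness=sc["smoothness"])
    for v in ENV_VARIABLES:
        write_raster(env[v], out_dir / f"env_{v}.tif")

    lc = synth_mod.generate_landcover(grid, sc["landcover_weights"], seed=seed + 1,
                                      patchiness=sc.get("patchiness", 4.0))
    write_raster(lc, out_dir / "landcover.tif")

    truth = synth_mod.default_truth()
    if sc.get("beta_true"):
        truth.beta_true = dict(sc["beta_true"])
    bias_centres = [tuple(c) for c in sc.get("bias_centres", [])]
    occ = synth_mod.simulate_occurrences(env, truth.beta_true, bias_centres,
                                         n=int(sc["n_occurrences"]), seed=seed + 2)
    occ.to_csv(out_dir / "occurrences.csv")

    class_params = {c: (truth.psi_true[c], truth.lambda_true[c]) for c in sc["plots"]}
    plots = synth_mod.simulate_plot_surveys(class_params, sc["plots"], seed=seed + 3)
    plots.to_csv(out_dir / "plots.csv", index=False)

    sun_cfg = sc.get("sunshine", {})
    stack = synth_mod.generate_sunshine_stack(
        grid, season_days=int(sun_cfg.get("season_days", 89)),
        hours_per_day=int(sun_cfg.get("hours_per_day", 12)), seed=seed + 4,
        **({"mean_bright_fraction": sun_cfg["mean_bright_fraction"]}
           if "mean_bright_fraction" in sun_cfg else {}))
    hours = foraging_mod.seasonal_foraging_hours(
        stack, bright_threshold=cfg["impact"].get("bright_threshold",
                                                  synth_mod.BRIGHT_THRESHOLD_MJ))
    write_raster(hours.layer, out_dir / "hours.tif")

    truth_record = {
        "beta_true": truth.beta_true,
        "bias_centres": bias_centres,
        "psi_true": truth.psi_true,
        "lambda_true": truth.lambda_true,
    }
    (out_dir / "sim_truth.json").write_text(json.dumps(truth_record, indent=1))


def stage_sdm(cfg: dict, out_dir: Path, seed: int) -> None:
    sc = cfg["sdm"]
    _require(out_dir, "sdm", "occurrences.csv")
    env = _read_env_stack(out_dir, "sdm")
    occ = read_occurrences(out_dir / "occurrences.csv", env.grid)
    bias = sdm_mod.build_bias_grid(occ, env.grid, bandwidth=sc.get("bandwidth"))
    write_raster(bias.layer, out_dir / "bias.tif")
    ensemble = sdm_mod.run_ensemble(
        occ, env, bias, n_runs=int(sc["n_runs"]),
        train_fraction=float(sc["train_fraction"]), seed=seed + 10,
        reg_lambda=float(sc["reg_lambda"]), background_size=int(sc["background_size"]))
    result = sdm_mod.predict_and_binarize(ensemble, env)
    write_raster(result.suitability, out_dir / "suitability.tif")
    write_raster(result.suitable_mask, out_dir / "suitable_mask.tif")
    (out_dir / "ensemble.json").write_text(json.dumps(ensemble.to_dict(), indent=1))
    if sc.get("importance"):
        imp = sdm_mod.variable_importance(ensemble, occ, env, bias, seed=seed + 11)
        imp.to_csv(out_dir / "importance.csv", index=False)


def stage_density(cfg: dict, out_dir: Path, seed: int) -> None:
    _require(out_dir, "density", "plots.csv")
    plots = read_plot_table(out_dir / "plots.csv")
    surveyed = density_mod.summarize_plots(plots)
    surveyed_classes = {e.land_cover_class for e in surveyed}
    other = [c for c, cat in DEFAULT_CATEGORIES.items()
             if c not in surveyed_classes and cat != "surveyed"]
    estimates = surveyed + density_mod.assign_nominal(other)
    density_mod.estimates_to_frame(estimates).to_csv(
        out_dir / "density_estimates.csv", index=False)

    kw_classes = cfg["density"].get("kw_classes", [])
    groups = [plots.loc[plots["class"] == c, "nests"].to_numpy()
              for c in kw_classes if (plots["class"] == c).any()]
    if len(groups) >= 2:
        kw = density_mod.kruskal_wallis(groups)
        (out_dir / "kruskal.json").write_text(json.dumps(
            {"H": kw.H, "df": kw.df, "p_value": kw.p_value, "classes": kw_classes}, indent=1))


def stage_extrapolate(cfg: dict, out_dir: Path, seed: int) -> None:
    lc_path = cfg["extrapolate"].get("landcover", out_dir / "landcover.tif")
    if not Path(lc_path).exists():
        raise DependencyError(
            f"stage 'extrapolate' requires a land-cover raster ({lc_path}); "
            "run 'simulate' or set extrapolate.landcover")
    _require(out_dir, "extrapolate", "suitable_mask.tif", "density_estimates.csv")
    landcover = read_raster(lc_path)
    mask = read_raster(out_dir / "suitable_mask.tif")
    est_df = pd.read_csv(out_dir / "density_estimates.csv")
    estimates = [density_mod.DensityEstimate(
        r["class"], int(r["n_plots"]), int(r["n_nests"]), int(r["density"]),
        float(r["occupancy"]), r["provenance"]) for r in est_df.to_dict("records")]
    areas = extrap_mod.class_area(landcover, mask)
    table = extrap_mod.extrapolate(areas, estimates)
    table.to_frame().to_csv(out_dir / "extrapolation.csv", index=False)


def stage_impact(cfg: dict, out_dir: Path, seed: int) -> None:
    _require(out_dir, "impact", "suitable_mask.tif", "landcover.tif",
             "density_estimates.csv")
    hours_path = cfg["impact"].get("hours_raster", out_dir / "hours.tif")
    if not Path(hours_path).exists():
        raise DependencyError(
            f"stage 'impact' requires a foraging-hours raster ({hours_path})")
    mask = read_raster(out_dir / "suitable_mask.tif")
    landcover = read_raster(out_dir / "landcover.tif")
    est_df = pd.read_csv(out_dir / "density_estimates.csv")
    estimates = [density_mod.DensityEstimate(
        r["class"], int(r["n_plots"]), int(r["n_nests"]), int(r["density"]),
        float(r["occupancy"]), r["provenance"]) for r in est_df.to_dict("records")]
    hours = foraging_mod.SeasonalHours(
        layer=read_raster(hours_path),
        bright_threshold=cfg["impact"].get("bright_threshold",
                                           synth_mod.BRIGHT_THRESHOLD_MJ))
    fp = foraging_mod.ForagingParams(**cfg["foraging"])
    impact = foraging_mod.impact_surface(mask, landcover, estimates,
                                         fp.success_rate, hours)
    write_raster(impact.layer, out_dir / "impact.tif")
    write_raster(impact.nests, out_dir / "nests.tif")


def stage_report(cfg: dict, out_dir: Path, seed: int) -> None:
    _require(out_dir, "report", "impact.tif", "extrapolation.csv",
             "hours.tif", "suitable_mask.tif")
    impact_layer = read_raster(out_dir / "impact.tif")
    hours_layer = read_raster(out_dir / "hours.tif")
    mask = read_raster(out_dir / "suitable_mask.tif")
    df = pd.read_csv(out_dir / "extrapolation.csv")
    body = df[df["class"] != "TOTAL"]
    table = extrap_mod.ExtrapolationTable(rows=[
        extrap_mod.ExtrapolationRow(
            r["class"], float(r["potential_ha"]), int(r["n_plots"]), int(r["n_nests"]),
            float(r["occupancy"]), int(r["density"]), int(r["occupied_ha"]),
            int(r["total_nests"]), float(r["occupied_ha_exact"]),
            float(r["total_nests_exact"]))
        for r in body.to_dict("records")])
    fp = foraging_mod.ForagingParams(**cfg["foraging"])
    in_mask = (mask.values > 0) & mask.valid
    if in_mask.any():
        mean_hours = float(hours_layer.values[in_mask].mean())
    else:
        mean_hours = float(hours_layer.values[hours_layer.valid].mean())
    hours_valid = hours_layer.values[hours_layer.valid]
    impact = foraging_mod.ImpactRaster(
        layer=impact_layer, nests=impact_layer, hours=hours_layer,
        success_rate=fp.success_rate)
    report = foraging_mod.national_totals(
        impact, table, fp.success_rate, mean_hours,
        hours_range=(float(hours_valid.min()), float(hours_valid.max())))
    report["suitable_cells"] = int(in_mask.sum())
    report["suitable_area_ha"] = in_mask.sum() * mask.grid.cell_area_ha
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "sdm": stage_sdm,
    "density": stage_density,
    "extrapolate": stage_extrapolate,
    "impact": stage_impact,
    "report": stage_report,
}


def run_stage(stage: str, config: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run one named stage with the merged config, writing into out_dir."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg = _merge(default_config(), config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = int(cfg.get("seed", 0)) if seed is None else int(seed)
    log.info("running stage %r (seed %d) -> %s", stage, s, out)
    _STAGE_FUNCS[stage](cfg, out, s)
    return out


def run_pipeline(config: dict | None, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run every stage in order; returns the artifact directory."""
    for stage in STAGES:
        run_stage(stage, config or {}, out_dir, seed=seed)
    return Path(out_dir)
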