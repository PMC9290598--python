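"""End-to-end pipeline: configuration, staging, logging, result tables.

One YAML configuration drives the whole analysis: load (or simulate) a
scene, build the terrain TIN, extract per-plot canopy metrics, fit the
per-group allometries and optionally the survey-covariate mixed models.
Outputs are three CSVs (per-plot metrics, group models, effect summaries)
with a ``#``-prefixed units header, plus a structured log line per stage so
every filter and parameter value is auditable.  Output is a pure function
of (inputs, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import fit_group_models
from .chm import ChmConfig, CanopyMetrics, EmptyPlotError, \
    compute_plot_metrics
from .effects import compute_sun_elevation, fit_cloud_model, fit_sun_model, \
    fit_wind_model
from .plots import PlotRecord, load_plot_table
from .pointcloud import load_point_cloud
from .synthetic import SceneParams, SyntheticScene, generate_scene
from .terrain import build_terrain

log = logging.getLogger("canopymass")

__all__ = ["PipelineConfig", "run_pipeline", "extract_metrics_table"]

_UNITS_HEADER = {
    "metrics": "# units: mean_height_m=m max_height_m=m area_m2=m^2 "
               "biomass_g=g biomass_g_m2=g/m^2 wind_speed_ms=m/s "
               "sun_elevation_deg=deg",
    "models": "# units: slope_g_m3=g/m^3 slope_se_g_m3=g/m^3 "
              "resid_se_g_m2=g/m^2 loocv_pct=%",
    "effects": "# units: estimate/se in response units (g/m^2) per "
               "predictor unit",
}


class ConfigError(ValueError):
    pass


class PipelineConfig:
    """Validated pipeline configuration (from a YAML mapping or file)."""

    REQUIRED = ("output_dir",)

    def __init__(self, mapping: dict):
        for key in self.REQUIRED:
            if key not in mapping:
                raise ConfigError(f"missing required config key: {key!r}")
        if ("inputs" not in mapping) == ("simulate" not in mapping):
            raise ConfigError(
                "config must name exactly one of 'inputs' or 'simulate'"
            )
        self.raw = mapping
        self.seed = int(mapping.get("seed", 0))
        self.output_dir = Path(mapping["output_dir"])
        chm = mapping.get("chm", {})
        self.chm = ChmConfig(**chm)
        self.terrain_mode = mapping.get("terrain", {}).get("mode", "joint")
        if self.terrain_mode not in ("joint", "per_plot"):
            raise ConfigError(
                f"terrain.mode must be 'joint' or 'per_plot', "
                f"got {self.terrain_mode!r}"
            )
        allom = mapping.get("allometry", {})
        self.grouping = allom.get("grouping", "pft")
        self.min_n = int(allom.get("min_n", 4))
        self.effects = tuple(mapping.get("effects", {}).get("run", ()))
        self.inputs = mapping.get("inputs")
        sim = mapping.get("simulate")
        if sim is not None:
            valid = {f.name for f in dataclass_fields(SceneParams)}
            bad = set(sim) - valid
            if bad:
                raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
            sim = dict(sim)
            sim.setdefault("seed", self.seed)
            self.simulate = SceneParams(**sim)
        else:
            self.simulate = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _stage(name: str, n_in: int, n_out: int, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s n_in=%d n_out=%d %s", name, n_in, n_out, kv)


def extract_metrics_table(cloud, plots: list[PlotRecord], chm: ChmConfig,
                          terrain_mode: str = "joint") -> pd.DataFrame:
    """Per-plot canopy metrics joined with plot attributes.

    Unreconstructed plots (no in-polygon points / all cells empty) appear
    with ``reconstructed = False`` and NaN metrics rather than aborting the
    run, mirroring how failed photogrammetric plots are reported.
    """
    if terrain_mode == "joint":
        terrain = build_terrain(np.vstack([p.corners for p in plots]))
    rows = []
    for plot in plots:
        if terrain_mode == "per_plot":
            terrain = build_terrain(plot.corners)
        row = {
            "plot_id": plot.plot_id, "species": plot.species,
            "pft": plot.pft, "survey_id": plot.survey_id,
            "area_m2": plot.area, "biomass_g": plot.biomass,
            "biomass_g_m2": plot.biomass_per_area,
            "wind_speed_ms": plot.wind_speed, "sky_code": plot.sky_code,
        }
        if (plot.timestamp and np.isfinite(plot.latitude)
                and np.isfinite(plot.longitude)):
            row["sun_elevation_deg"] = compute_sun_elevation(
                plot.latitude, plot.longitude, plot.timestamp
            )
        else:
            row["sun_elevation_deg"] = np.nan
        try:
            m: CanopyMetrics = compute_plot_metrics(
                cloud, plot, terrain, chm
            )
            row.update({
                "mean_height_m": m.mean_height,
                "max_height_m": m.max_height,
                "filled_fraction": m.filled_fraction,
                "n_points": m.n_points, "reconstructed": True,
            })
        except EmptyPlotError:
            row.update({
                "mean_height_m": np.nan, "max_height_m": np.nan,
                "filled_fraction": 0.0, "n_points": 0,
                "reconstructed": False,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, units_key: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_UNITS_HEADER[units_key] + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(config) -> dict[str, pd.DataFrame]:
    """Run the configured analysis; returns and writes the result tables."""
    if not isinstance(config, PipelineConfig):
        config = (PipelineConfig.from_yaml(config)
                  if isinstance(config, (str, Path))
                  else PipelineConfig(config))
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        scene: SyntheticScene = generate_scene(config.simulate)
        cloud, plots = scene.cloud, scene.plots
        _stage("simulate", config.simulate.n_plots, len(cloud),
               seed=config.simulate.seed,
               point_density=config.simulate.point_density,
               wind=config.simulate.wind_speed)
        truth_path = out / "truth.csv"
        scene.truth.to_csv(truth_path, index=False, float_format="%.8g")
    else:
        inp = config.inputs
        for key in ("point_cloud", "plot_corners"):
            if key not in inp:
                raise ConfigError(f"missing required config key: inputs.{key}")
        cloud = load_point_cloud(inp["point_cloud"])
        plots = load_plot_table(inp["plot_corners"],
                                inp.get("plot_attributes"))
        _stage("load", 2, len(plots), cloud_points=len(cloud))

    metrics = extract_metrics_table(cloud, plots, config.chm,
                                    config.terrain_mode)
    _stage("metrics", len(plots), int(metrics["reconstructed"].sum()),
           resolution=config.chm.resolution, window=config.chm.idw_window,
           power=config.chm.idw_power, mean_over=config.chm.mean_over)
    _write_csv(metrics.round(9), out / "plot_metrics.csv", "metrics")

    obs = metrics[metrics["reconstructed"]].copy()
    models = fit_group_models(obs, grouping=config.grouping,
                              min_n=config.min_n)
    _stage("allometry", len(obs), int((~models["skipped"]).sum()),
           grouping=config.grouping, min_n=config.min_n)
    _write_csv(models, out / "group_models.csv", "models")

    effect_rows = []
    for which in config.effects:
        fitter = {"wind": fit_wind_model, "sun": fit_sun_model,
                  "cloud": fit_cloud_model}.get(which)
        if fitter is None:
            raise ConfigError(f"unknown effect model {which!r}")
        try:
            fit = fitter(obs)
        except ValueError as exc:
            log.warning("stage=effects model=%s skipped: %s", which, exc)
            continue
        for _, r in fit.coef.iterrows():
            effect_rows.append({
                "model": which, "method": fit.method, "term": r["term"],
                "estimate": r["estimate"], "se": r["se"],
                "stat": r["stat"], "p": r["p"],
                "converged": fit.converged,
            })
        _stage("effects", len(obs), len(fit.coef), model=which,
               method=fit.method, converged=fit.converged)
    effects = pd.DataFrame(
        effect_rows,
        columns=["model", "method", "term", "estimate", "se", "stat", "p",
                 "converged"],
    )
    _write_csv(effects, out / "effect_models.csv", "effects")

    return {"metrics": metrics, "models": models, "effects": effects}
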