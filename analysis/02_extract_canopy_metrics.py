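#!/usr/bin/env python
"""Extract per-plot canopy height metrics from the reference survey.

Reads the LAS cloud and plot tables written by 01_simulate_scenes.py,
builds the TIN terrain from all plot corners, runs the canopy-height-model
chain (clip, height-above-ground with zero clamping, 1 cm local-maxima
grid, 7x7 power-1 IDW fill) and writes per-plot metrics plus one example
canopy height raster.
"""

from pathlib import Path

import pandas as pd

from canopymass import (
    ChmConfig, build_terrain, compute_plot_metrics, load_plot_table,
    load_point_cloud, write_chm_raster,
)
import numpy as np

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cloud = load_point_cloud(ROOT / "scene" / "cloud.las")
    plots = load_plot_table(ROOT / "scene" / "plot_corners.csv",
                            ROOT / "scene" / "plot_attributes.csv")
    terrain = build_terrain(np.vstack([p.corners for p in plots]))
    cfg = ChmConfig()

    rows = []
    example_grid = None
    for plot in plots:
        metrics, grid = compute_plot_metrics(cloud, plot, terrain, cfg,
                                             return_grid=True)
        if example_grid is None:
            example_grid = grid
        rows.append({
            "plot_id": plot.plot_id, "species": plot.species,
            "pft": plot.pft, "survey_id": plot.survey_id,
            "area_m2": plot.area, "biomass_g": plot.biomass,
            "biomass_g_m2": plot.biomass_per_area,
            "wind_speed_ms": plot.wind_speed, "sky_code": plot.sky_code,
            "mean_height_m": metrics.mean_height,
            "max_height_m": metrics.max_height,
            "filled_fraction": metrics.filled_fraction,
            "n_points": metrics.n_points,
        })
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "plot_metrics.csv", index=False)
    write_chm_raster(example_grid, ROOT / "example_chm.asc")

    truth = pd.read_csv(ROOT / "scene" / "truth.csv")
    joined = table.merge(truth[["plot_id", "true_mean_height_m"]],
                         on="plot_id")
    bias = (joined["mean_height_m"] - joined["true_mean_height_m"]).mean()
    print(f"extracted metrics for {len(table)}/{len(plots)} plots "
          f"-> {ROOT / 'plot_metrics.csv'}")
    print(f"mean height bias vs truth: {bias:+.4f} m "
          f"(vertical noise 0.01 m, wind 1.5 m/s at k=0.05)")
    print(f"mean fill fraction after IDW: "
          f"{table['filled_fraction'].mean():.3f}")


if __name__ == "__main__":
    main()
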