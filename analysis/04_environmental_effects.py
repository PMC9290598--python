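#!/usr/bin/env python
"""Test wind, sun-elevation and cloud effects on height-biomass relations.

Two designs: (a) a full-pipeline experiment — noise-free scenes surveyed
at 0, 2 and 4 m/s with 5% reconstructed-height loss per m/s, showing the
fitted density rise with wind; (b) a multi-survey observation-level
experiment (300 plots, 10 surveys) fitted with the gamma-identity mixed
model (wind) and Gaussian mixed models (sun, cloud).  Writes the
coefficient tables, the slope-vs-wind table with 83% CIs, and predicted
height-biomass curves at three wind speeds.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from canopymass import (
    ChmConfig, SceneParams, extract_metrics_table, fit_cloud_model,
    fit_sun_model, fit_wind_model, fit_zero_intercept, generate_scene,
    simulate_effect_curves, simulate_observations, slope_vs_covariate,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def full_pipeline_wind() -> pd.DataFrame:
    rows = []
    for j, w in enumerate((0.0, 2.0, 4.0)):
        scene = generate_scene(SceneParams(
            seed=500 + j, n_plots=30, pft_mix=("graminoid",),
            plot_size=0.5, point_density=10000, vertical_noise_sd=0.0,
            biomass_cv=0.0, roughness=0.0, wind_speed=w,
            wind_attenuation=0.05,
        ))
        metrics = extract_metrics_table(scene.cloud, scene.plots,
                                        ChmConfig())
        m = fit_zero_intercept(metrics, group=f"wind={w}")
        rows.append({"group": "graminoid", "wind_speed_ms": w,
                     "slope_g_m3": m.slope, "slope_se_g_m3": m.slope_se})
    return pd.DataFrame(rows)


def main() -> None:
    slopes = full_pipeline_wind()
    ci_table = slope_vs_covariate(slopes, "wind_speed_ms", ci_level=0.83)
    ci_table.to_csv(ROOT / "slope_vs_wind.csv", index=False)
    print("full-pipeline fitted density vs survey wind speed "
          "(83% CI) -> results/slope_vs_wind.csv")
    print(ci_table.round(1).to_string(index=False))
    rising = slopes["slope_g_m3"].is_monotonic_increasing
    print(f"slopes strictly increase with wind: {rising} "
          "(shorter reconstructions at fixed biomass)\n")

    obs = simulate_observations(300, seed=510, wind_attenuation=0.05,
                                cloudy_fraction=0.2)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = {"wind": fit_wind_model(obs), "sun": fit_sun_model(obs),
                "cloud": fit_cloud_model(obs)}
    for name, fit in fits.items():
        inter = fit.interaction
        print(f"{name:>5} model [{fit.method}] height x {fit.covariate}: "
              f"{inter['estimate']:+.1f} +- {inter['se']:.1f} "
              f"(p = {inter['p']:.2g})")
        for _, r in fit.coef.iterrows():
            rows.append({"model": name, "method": fit.method, **r})
    pd.DataFrame(rows).to_csv(ROOT / "effect_models.csv", index=False)

    curves = simulate_effect_curves(
        fits["wind"], [1.0, 3.0, 5.0], np.linspace(0.1, 1.4, 27)
    )
    curves.to_csv(ROOT / "wind_effect_curves.csv", index=False)
    print("\nwind generated with 5% height loss per m/s: expect a clear "
          "positive interaction;")
    print("sun and cloud generated with no effect: expect "
          "non-significant interactions.")
    print("coefficients -> results/effect_models.csv; predicted curves "
          "-> results/wind_effect_curves.csv")


if __name__ == "__main__":
    main()
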