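"""Sun geometry and wind/sun/cloud mixed models."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canopymass import (
    compute_sun_elevation, fit_cloud_model, fit_sun_model, fit_wind_model,
    simulate_effect_curves, simulate_observations, slope_vs_covariate,
)
from canopymass.effects import CLOUDY_SKY_CODE


# ------------------------------------------------------------ sun position

def test_equinox_noon_at_equator_near_zenith():
    # 2019 March equinox ~ 21:58 UTC on the 20th; solar noon at lon 0 is
    # ~12:08 UTC (equation of time): sun within a degree of the zenith
    elev = compute_sun_elevation(0.0, 0.0, "2019-03-20T12:08:00+00:00")
    assert elev > 89.0


def test_polar_night_negative_elevation():
    elev = compute_sun_elevation(71.0, 0.0, "2019-12-21T00:00:00+00:00")
    assert elev < 0.0


def test_midnight_sun_positive_elevation():
    elev = compute_sun_elevation(71.0, 0.0, "2019-06-21T00:00:00+00:00")
    assert elev > 0.0


@pytest.mark.parametrize("lat,lon,when,expected", [
    # noon elevation ~ 90 - |lat - declination|; declination +-23.44 at the
    # solstices and 0 at the equinoxes, solar noon shifted by the equation
    # of time and longitude
    (40.0, 0.0, "2019-06-21T11:58:00+00:00", 90 - abs(40 - 23.44)),
    (40.0, 0.0, "2019-12-22T11:57:00+00:00", 90 - abs(40 + 23.44)),
    (-35.0, 0.0, "2019-12-22T11:57:00+00:00", 90 - abs(-35 + 23.44)),
    (52.0, 0.0, "2019-03-20T12:08:00+00:00", 90 - 52),
    (0.0, 90.0, "2019-09-23T05:52:00+00:00", 90.0),
    (65.0, -20.0, "2019-06-21T13:18:00+00:00", 90 - abs(65 - 23.44)),
])
def test_solar_noon_spot_checks(lat, lon, when, expected):
    # refraction is negligible this high; 0.6 deg tolerance absorbs the
    # few-minutes imprecision of the stated solar-noon times
    assert compute_sun_elevation(lat, lon, when) == pytest.approx(
        expected, abs=0.6
    )


def test_elevation_bounded():
    for hour in range(0, 24, 3):
        e = compute_sun_elevation(40.0, -5.0, f"2019-07-15T{hour:02d}:00:00")
        assert -90.0 <= e <= 90.0


# ------------------------------------------------------------ wind model

def test_wind_attenuation_detected_positive():
    obs = simulate_observations(300, seed=11, wind_attenuation=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_wind_model(obs)
    inter = fit.interaction
    assert inter["estimate"] > 0
    assert inter["p"] < 0.05
    assert fit.converged


def test_wind_null_interaction_near_zero():
    """Without a generated wind effect the interaction is within 2 SE of
    zero (single replicate smoke; full calibration in the acceptance
    suite)."""
    obs = simulate_observations(300, seed=1002, wind_attenuation=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_wind_model(obs)
    inter = fit.interaction
    assert abs(inter["estimate"]) < 2 * inter["se"]


def test_single_wind_value_rejected():
    obs = simulate_observations(60, seed=5)
    obs["wind_speed_ms"] = 2.0
    with pytest.raises(ValueError, match="wind"):
        fit_wind_model(obs)


def test_succulents_excluded():
    obs = simulate_observations(
        120, seed=6, pfts=("graminoid", "shrub", "succulent")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_wind_model(obs)
    assert "succulent" not in fit.group_sizes


def test_zero_biomass_shifted_for_gamma():
    obs = simulate_observations(100, seed=9)
    obs.loc[obs.index[:2], "biomass_g_m2"] = 0.0
    with pytest.warns(UserWarning, match="shifted"):
        fit_wind_model(obs)


# ------------------------------------------------------------ sun model

def test_sun_null_single_replicate():
    """No generated sun effect: non-significant interaction (smoke; the
    full 100-replicate calibration lives in the acceptance suite)."""
    obs = simulate_observations(300, seed=2001, sun_attenuation=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_sun_model(obs)
    assert fit.interaction["p"] > 0.05


def test_sun_effect_sign_recovered():
    # lower sun -> stronger attenuation -> steeper biomass-per-height at
    # high sun: negative height:sun? attenuation decreases with sun, so
    # reconstructed height rises with sun and slope b/h falls: negative
    obs = simulate_observations(400, seed=21, sun_attenuation=0.3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_sun_model(obs)
    assert fit.interaction["estimate"] < 0
    assert fit.interaction["p"] < 0.05


def test_sky_filter_empty_rejected():
    obs = simulate_observations(50, seed=3, cloudy_fraction=1.0)
    with pytest.raises(ValueError):
        fit_sun_model(obs)


# ------------------------------------------------------------ cloud model

def test_sky_code_binarisation():
    codes = pd.Series([3, 6, 9])
    assert ((codes >= CLOUDY_SKY_CODE) == pd.Series(
        [False, True, True]
    )).all()


def test_cloud_null_within_2se():
    cover = 0
    n_rep = 15
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_rep):
            obs = simulate_observations(300, seed=3000 + rep,
                                        cloudy_fraction=0.5)
            fit = fit_cloud_model(obs)
            inter = fit.interaction
            if abs(inter["estimate"]) < 2 * inter["se"]:
                cover += 1
    assert cover >= 0.9 * n_rep


def test_cloud_single_level_rejected():
    obs = simulate_observations(50, seed=4, cloudy_fraction=0.0)
    with pytest.raises(ValueError, match="cloudy"):
        fit_cloud_model(obs)


def test_cloud_group_sizes_annotated():
    obs = simulate_observations(200, seed=13, cloudy_fraction=0.3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cloud_model(obs)
    assert set(fit.group_sizes) == {"clear", "cloudy"}
    assert sum(fit.group_sizes.values()) == len(obs)


# ------------------------------------------------------------ CI table

def test_83pct_ci_z_value():
    models = pd.DataFrame({
        "group": ["shrub"], "wind_speed_ms": [2.0],
        "slope_g_m3": [3000.0], "slope_se_g_m3": [100.0],
    })
    table = slope_vs_covariate(models, "wind_speed_ms", ci_level=0.83)
    z = stats.norm.ppf(0.915)
    assert z == pytest.approx(1.37220, abs=1e-5)
    assert table["ci_lo"].iloc[0] == pytest.approx(3000 - 100 * z)
    assert table["ci_hi"].iloc[0] == pytest.approx(2862.8 + 274.4, abs=0.1)


def test_zero_level_degenerate_ci():
    models = pd.DataFrame({
        "group": ["a"], "w": [1.0], "slope_g_m3": [500.0],
        "slope_se_g_m3": [50.0],
    })
    t = slope_vs_covariate(models, "w", ci_level=0.0)
    assert t["ci_lo"].iloc[0] == pytest.approx(500.0)
    assert t["ci_hi"].iloc[0] == pytest.approx(500.0)


def test_ci_monotone_in_level_and_scales_with_se():
    models = pd.DataFrame({
        "group": ["a"], "w": [1.0], "slope_g_m3": [500.0],
        "slope_se_g_m3": [50.0],
    })
    w83 = slope_vs_covariate(models, "w", 0.83)
    w95 = slope_vs_covariate(models, "w", 0.95)
    width83 = w83["ci_hi"].iloc[0] - w83["ci_lo"].iloc[0]
    width95 = w95["ci_hi"].iloc[0] - w95["ci_lo"].iloc[0]
    assert width95 > width83
    models2 = models.assign(slope_se_g_m3=100.0)
    width2 = slope_vs_covariate(models2, "w", 0.83)
    assert (width2["ci_hi"].iloc[0] - width2["ci_lo"].iloc[0]) == \
        pytest.approx(2 * width83)


def test_missing_se_skipped_with_warning():
    models = pd.DataFrame({
        "group": ["a", "b"], "w": [1.0, 2.0],
        "slope_g_m3": [500.0, 600.0],
        "slope_se_g_m3": [50.0, np.nan],
    })
    with pytest.warns(UserWarning, match="skipped"):
        t = slope_vs_covariate(models, "w")
    assert t["group"].tolist() == ["a"]


# ------------------------------------------------------------ curves

def _converged_fit():
    obs = simulate_observations(300, seed=30, wind_attenuation=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_wind_model(obs), obs


def test_zero_interaction_curves_coincide():
    fit, _ = _converged_fit()
    # force a zero interaction and zero wind main effect
    fit.coef.loc[fit.coef["term"] == "height:wind", "estimate"] = 0.0
    fit.coef.loc[fit.coef["term"] == "wind", "estimate"] = 0.0
    curves = simulate_effect_curves(fit, [0.0, 2.0, 4.0],
                                    np.linspace(0.1, 1.0, 5))
    by_level = curves.groupby("wind")["predicted_g_m2"].apply(list)
    np.testing.assert_allclose(by_level.iloc[0], by_level.iloc[1])
    np.testing.assert_allclose(by_level.iloc[0], by_level.iloc[2])


def test_positive_interaction_steepens_curves():
    fit, _ = _converged_fit()
    curves = simulate_effect_curves(fit, [0.0, 4.0],
                                    np.linspace(0.1, 1.0, 5))
    slope_by_level = curves.groupby("wind").apply(
        lambda g: np.polyfit(g["mean_height_m"], g["predicted_g_m2"], 1)[0],
        include_groups=False,
    )
    assert slope_by_level.loc[4.0] > slope_by_level.loc[0.0]


def test_predictions_match_fitted_values_at_design_points():
    fit, obs = _converged_fit()
    beta = fit.params()
    h = obs["mean_height_m"].to_numpy()[:10]
    w = obs["wind_speed_ms"].to_numpy()[:10]
    X = np.column_stack([np.ones(10), h, w, h * w])
    expect = X @ beta
    for hh, ww, mu in zip(h, w, expect):
        got = simulate_effect_curves(fit, [ww], [hh])
        assert got["predicted_g_m2"].iloc[0] == pytest.approx(mu, rel=1e-9)


def test_extrapolation_warns():
    fit, _ = _converged_fit()
    with pytest.warns(UserWarning, match="extrapolat"):
        simulate_effect_curves(fit, [99.0], [0.5])


def test_ci_bounds_ordered():
    fit, _ = _converged_fit()
    curves = simulate_effect_curves(fit, [1.0], np.linspace(0.1, 1, 8))
    assert (curves["ci_lo"] <= curves["ci_hi"]).all()
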