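"""Synthetic vegetation surveys with known ground truth.

Emulates what a photogrammetric survey of low-stature vegetation delivers
downstream of structure-from-motion: a dense point cloud (~5 mm ground
sampling, i.e. ~40 000 points per m^2) over harvest plots laid out on a
terrain, plus a plot table with dry biomass and survey covariates.  Every
quantity the pipeline estimates has a recorded true value, so estimator and
pipeline recovery can be tested exactly.

The generative model inverts the analysis assumptions:

* a true canopy height field h*(x, y) >= 0 per plot (smooth sward or an
  envelope of ellipsoidal crowns);
* biomass per area b = rho * hbar* * exp(delta - sigma^2/2), with rho the
  PFT's volumetric density (g m^-3) and delta lognormal noise chosen so
  E[b] = rho * hbar* — zero height implies zero biomass by construction;
* reconstructed points z = terrain + h* . (1 - k w U) + eps, with U uniform
  per point: wind (speed w, attenuation rate k) removes matched canopy-top
  points heterogeneously, which is how non-concurrent image capture of
  moving foliage degrades reconstructions, and eps is vertical
  reconstruction noise.

Default densities are realistic per-PFT volumetric biomass densities for
low-stature vegetation, spanning ferns (~1100 g m^-3) to succulents
(~11 500 g m^-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .plots import PlotRecord, PFTS
from .pointcloud import PointCloud
from .terrain import build_terrain

__all__ = [
    "PFT_DENSITY", "SceneParams", "SyntheticScene", "generate_canopy_field",
    "sample_point_cloud", "assign_biomass", "generate_scene",
    "simulate_observations",
]

# volumetric AGB density rho (g m^-3) by plant functional type
PFT_DENSITY = {
    "fern": 1096.0,
    "forb": 1191.0,
    "graminoid": 2898.0,
    "shrub": 3214.0,
    "tree": 5572.0,
    "succulent": 11532.0,
}


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters for one synthetic survey.

    Heights are metres, densities g m^-3, wind speed m s^-1.  The wind
    attenuation ``k`` is the fractional height loss per unit wind speed at
    the point level; ``k * wind_speed`` must stay below 1.
    """

    seed: int = 0
    n_plots: int = 30
    plot_size: float = 1.0                    # m, square plots (>= 0.5)
    spacing: float = 1.0                      # m between plot edges
    terrain: str = "planar"                   # flat | planar | smooth_random
    terrain_slope: tuple[float, float] = (0.05, -0.03)
    terrain_amplitude: float = 0.15           # smooth_random only
    terrain_length_scale: float = 5.0         # m, smooth_random only
    base_elevation: float = 100.0
    pft_mix: tuple[str, ...] = PFTS
    density: dict = field(default_factory=lambda: dict(PFT_DENSITY))
    canopy: str = "sward"                     # sward | crowns
    height_range: tuple[float, float] = (0.05, 1.5)
    roughness: float = 0.3                    # relative within-plot variation
    canopy_length_scale: float = 0.25         # m
    n_crowns: int = 3
    point_density: float = 40000.0            # points m^-2 (~5 mm sampling)
    vertical_noise_sd: float = 0.01           # m (~2 px at 5 mm GSD)
    dropout_fraction: float = 0.0
    biomass_cv: float = 0.2                   # lognormal CV of biomass noise
    wind_speed: float = 0.0
    wind_attenuation: float = 0.0             # k, per (m s^-1)
    sun_elevation: float = 45.0
    sky_code: int = 2
    survey_id: str = "synthetic-1"
    timestamp: str = "2019-07-15T12:00:00+00:00"
    latitude: float = 40.0
    longitude: float = -5.0
    corner_z_noise_sd: float = 0.0            # GNSS vertical noise on corners

    def __post_init__(self) -> None:
        if self.plot_size < 0.5:
            raise ValueError("plot_size below the 0.5 m protocol minimum")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.wind_attenuation < 0:
            raise ValueError("wind_attenuation must be >= 0")
        if self.wind_attenuation * self.wind_speed >= 1:
            raise ValueError("k * wind_speed must be < 1")
        for pft in self.pft_mix:
            if self.density.get(pft, 0) <= 0:
                raise ValueError(f"non-positive density for PFT {pft!r}")


@dataclass
class SyntheticScene:
    params: SceneParams
    cloud: PointCloud
    plots: list[PlotRecord]
    truth: pd.DataFrame   # plot_id, pft, true_mean_height_m, density_g_m3,
                          # biomass_g_m2, biomass_g


# ------------------------------------------------------------ canopy fields

def _smooth_random_field(rng: np.random.Generator, length_scale: float,
                         n_modes: int = 24) -> Callable:
    """Zero-mean, unit-variance smooth random function via random cosines."""
    kmag = rng.rayleigh(scale=1.0 / (2 * math.pi * length_scale),
                        size=n_modes) * (2 * math.pi)
    theta = rng.uniform(0, 2 * math.pi, n_modes)
    phase = rng.uniform(0, 2 * math.pi, n_modes)
    kx = kmag * np.cos(theta)
    ky = kmag * np.sin(theta)
    amp = math.sqrt(2.0 / n_modes)

    def f(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return amp * np.cos(
            x[..., None] * kx + y[..., None] * ky + phase
        ).sum(axis=-1)

    return f


def generate_canopy_field(params: SceneParams, extent: float,
                          mean_height: float,
                          rng: np.random.Generator) -> Callable:
    """True canopy height function h*(x, y) >= 0 over [0, extent]^2.

    ``sward``: a smooth positive random field with the requested plot mean
    level and relative roughness (roughness 0 gives a constant sward).
    ``crowns``: the upper envelope of ellipsoidal crown caps on bare ground.
    """
    if params.canopy == "sward":
        if params.roughness == 0:
            return lambda x, y: np.full(np.broadcast(
                np.asarray(x), np.asarray(y)).shape, mean_height)
        g = _smooth_random_field(rng, params.canopy_length_scale)
        sd = params.roughness * mean_height

        def h(x, y):
            return np.maximum(mean_height + sd * g(x, y), 0.0)

        return h
    if params.canopy == "crowns":
        n = params.n_crowns
        cx = rng.uniform(0.15 * extent, 0.85 * extent, n)
        cy = rng.uniform(0.15 * extent, 0.85 * extent, n)
        r = rng.uniform(0.15 * extent, 0.4 * extent, n)
        hmax = mean_height * rng.uniform(1.5, 2.5, n)

        def h(x, y):
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            d2 = ((x[..., None] - cx) ** 2 + (y[..., None] - cy) ** 2) / r**2
            caps = hmax * np.sqrt(np.clip(1.0 - d2, 0.0, None))
            return caps.max(axis=-1)

        return h
    raise ValueError(f"unknown canopy generator {params.canopy!r}")


def field_mean(h: Callable, extent: float, resolution: float = 0.005
               ) -> float:
    """Numerical plot mean of a canopy field (midpoint rule)."""
    n = max(2, int(round(extent / resolution)))
    c = (np.arange(n) + 0.5) * (extent / n)
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return float(h(xx.ravel(), yy.ravel()).mean())


# ------------------------------------------------------------ sampling

def sample_point_cloud(h: Callable, terrain_z: Callable, origin, extent,
                       params: SceneParams,
                       rng: np.random.Generator) -> PointCloud:
    """Photogrammetry-like sample of a canopy field over one plot.

    Uniform planar sampling at ``point_density`` (Poisson count) with
    dropout; per point the canopy height is attenuated by (1 - k w U),
    U ~ Uniform(0, 1), plus Gaussian vertical noise, and the point never
    falls below the terrain.
    """
    x0, y0 = origin
    area = extent * extent
    lam = params.point_density * area * (1.0 - params.dropout_fraction)
    n = int(rng.poisson(lam))
    if n == 0:
        return PointCloud(np.empty((0, 3)))
    xl = rng.uniform(0.0, extent, n)
    yl = rng.uniform(0.0, extent, n)
    hv = h(xl, yl)
    kw = params.wind_attenuation * params.wind_speed
    if kw > 0:
        hv = hv * (1.0 - kw * rng.uniform(0.0, 1.0, n))
    z_ground = terrain_z(x0 + xl, y0 + yl)
    z = z_ground + hv
    if params.vertical_noise_sd > 0:
        z = z + rng.normal(0.0, params.vertical_noise_sd, n)
    z = np.maximum(z, z_ground)
    return PointCloud(np.column_stack([x0 + xl, y0 + yl, z]))


def assign_biomass(mean_height: float, rho: float, area: float,
                   biomass_cv: float,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Draw (biomass g m^-2, total g) with mean rho * hbar* per m^2.

    Lognormal multiplicative noise with the mean-preserving -sigma^2/2
    correction, so the allometric slope is unbiased by construction.
    """
    if rho <= 0:
        raise ValueError("density rho must be positive")
    b = rho * mean_height
    if biomass_cv > 0 and b > 0:
        sigma2 = math.log(1.0 + biomass_cv**2)
        b *= math.exp(rng.normal(0.0, math.sqrt(sigma2)) - sigma2 / 2.0)
    return b, b * area


# ------------------------------------------------------------ full scenes

def _terrain_function(params: SceneParams,
                      rng: np.random.Generator) -> Callable:
    if params.terrain == "flat":
        return lambda x, y: np.full(
            np.broadcast(np.asarray(x), np.asarray(y)).shape,
            params.base_elevation,
        )
    if params.terrain == "planar":
        sx, sy = params.terrain_slope

        def plane(x, y):
            return (params.base_elevation + sx * np.asarray(x, float)
                    + sy * np.asarray(y, float))

        return plane
    if params.terrain == "smooth_random":
        g = _smooth_random_field(rng, params.terrain_length_scale)

        def rough(x, y):
            return params.base_elevation + params.terrain_amplitude * g(x, y)

        return rough
    raise ValueError(f"unknown terrain kind {params.terrain!r}")


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Lay out plots on a grid, build terrain, sample clouds, assign truth.

    Fully deterministic given ``params`` (all randomness flows from
    ``params.seed``).  Plots cycle through ``pft_mix`` so every PFT in the
    mix is represented.
    """
    rng = np.random.default_rng(params.seed)
    terrain_z = _terrain_function(params, rng)
    side = params.plot_size
    pitch = side + params.spacing
    n_cols = max(1, int(math.ceil(math.sqrt(params.n_plots))))
    h_lo, h_hi = params.height_range
    clouds = []
    plots: list[PlotRecord] = []
    truth_rows = []
    for i in range(params.n_plots):
        row, col = divmod(i, n_cols)
        x0, y0 = col * pitch, row * pitch
        pft = params.pft_mix[i % len(params.pft_mix)]
        rho = params.density[pft]
        target_mean = rng.uniform(h_lo, h_hi)
        h = generate_canopy_field(params, side, target_mean, rng)
        true_mean = field_mean(h, side)
        cloud = sample_point_cloud(h, terrain_z, (x0, y0), side, params, rng)
        b_per_area, b_total = assign_biomass(
            true_mean, rho, side * side, params.biomass_cv, rng
        )
        corners_xy = np.array([
            [x0, y0], [x0 + side, y0], [x0 + side, y0 + side],
            [x0, y0 + side],
        ])
        corner_z = terrain_z(corners_xy[:, 0], corners_xy[:, 1])
        if params.corner_z_noise_sd > 0:
            corner_z = corner_z + rng.normal(
                0.0, params.corner_z_noise_sd, 4
            )
        plots.append(PlotRecord(
            plot_id=f"plot-{i:03d}",
            corners=np.column_stack([corners_xy, corner_z]),
            biomass=b_total, species=f"{pft}_sp1", pft=pft,
            survey_id=params.survey_id, wind_speed=params.wind_speed,
            timestamp=params.timestamp, latitude=params.latitude,
            longitude=params.longitude, sky_code=params.sky_code,
        ))
        clouds.append(cloud.xyz)
        truth_rows.append({
            "plot_id": f"plot-{i:03d}", "pft": pft, "species": f"{pft}_sp1",
            "true_mean_height_m": true_mean, "density_g_m3": rho,
            "biomass_g_m2": b_per_area, "biomass_g": b_total,
            "wind_speed_ms": params.wind_speed,
            "survey_id": params.survey_id,
        })
    cloud = PointCloud(np.vstack([c for c in clouds if len(c)])
                       if clouds else np.empty((0, 3)))
    truth = pd.DataFrame(truth_rows)
    return SyntheticScene(params=params, cloud=cloud, plots=plots,
                          truth=truth)


def scene_terrain(scene: SyntheticScene):
    """TIN built from the union of the scene's plot corners."""
    corners = np.vstack([p.corners for p in scene.plots])
    return build_terrain(corners)


# ------------------------------------------------ observation-level draws

def simulate_observations(n_plots: int, seed: int,
                          pfts=("fern", "forb", "graminoid", "shrub",
                                "tree"),
                          n_surveys: int = 10,
                          wind_range=(0.0, 6.0),
                          wind_attenuation: float = 0.0,
                          sun_range=(10.0, 60.0),
                          sun_attenuation: float = 0.0,
                          height_range=(0.05, 1.5),
                          height_noise_sd: float = 0.01,
                          biomass_cv: float = 0.2,
                          cloudy_fraction: float = 0.0) -> pd.DataFrame:
    """Plot-level observations without the point-cloud stage.

    Reconstructed mean height is the true height attenuated by
    (1 - k_wind w) and (1 - k_sun (s_max - s)/s_max) plus measurement noise;
    biomass comes from the true height.  Survey covariates (wind, sun
    elevation, sky code) are drawn per survey and shared by its plots.
    This is the fast generator for mixed-model calibration studies; the
    point-cloud route in :func:`generate_scene` is the full-pipeline one.
    """
    rng = np.random.default_rng(seed)
    wind = rng.uniform(*wind_range, n_surveys)
    sun = rng.uniform(*sun_range, n_surveys)
    cloudy = rng.uniform(size=n_surveys) < cloudy_fraction
    sky = np.where(cloudy, rng.integers(6, 11, n_surveys),
                   rng.integers(0, 6, n_surveys))
    survey = rng.integers(0, n_surveys, n_plots)
    pft = rng.choice(pfts, n_plots)
    rho = np.array([PFT_DENSITY[p] for p in pft])
    h_true = rng.uniform(*height_range, n_plots)
    atten = 1.0 - wind_attenuation * wind[survey]
    if sun_attenuation > 0:
        s_hi = sun_range[1]
        atten = atten * (1.0 - sun_attenuation * (s_hi - sun[survey]) / s_hi)
    h_rec = np.maximum(
        h_true * atten + rng.normal(0.0, height_noise_sd, n_plots), 1e-4
    )
    sigma2 = math.log(1.0 + biomass_cv**2)
    b = rho * h_true * np.exp(
        rng.normal(0.0, math.sqrt(sigma2), n_plots) - sigma2 / 2.0
    )
    return pd.DataFrame({
        "plot_id": [f"obs-{i:04d}" for i in range(n_plots)],
        "pft": pft, "species": [f"{p}_sp1" for p in pft],
        "survey_id": [f"survey-{s:02d}" for s in survey],
        "true_mean_height_m": h_true, "mean_height_m": h_rec,
        "biomass_g_m2": b, "wind_speed_ms": wind[survey],
        "sun_elevation_deg": sun[survey], "sky_code": sky[survey],
    })
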