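# canopymass

Predicting dry aboveground biomass (AGB) of low-stature vegetation —
grasses, shrubs, herbs, small trees — from drone-photogrammetry point
clouds. Non-forest ecosystems cover most of the land surface but are poorly
served by satellite biomass products; centimetre-grain canopy height from
structure-from-motion (SfM) photogrammetry, calibrated against harvested
plots, closes that gap. This package implements the analysis chain from a
georeferenced vegetation point cloud and a table of surveyed harvest plots
to per-group allometric models and tests of survey-condition artefacts,
plus a synthetic-survey generator so every stage is testable against known
ground truth.

## The model

For each harvest plot, mean canopy height h&#772; is extracted from the point
cloud: the cloud is clipped to the surveyed plot polygon, each point's
height above a TIN terrain (Delaunay triangulation of the GNSS plot
corners) is computed with negative heights clamped to zero, heights are
gridded at 0.01 m taking the per-cell **maximum**, empty cells are filled by
inverse-distance weighting over the centred 7 × 7 cell window with power 1
(one pass; cells with no populated neighbour stay empty), and h&#772; is the
mean of the populated cells.

Biomass per area b (g m⁻²) is then modelled through the origin,

```
b = β·h̄ + ε,     β̂ = Σ h̄ᵢbᵢ / Σ h̄ᵢ²
```

so zero height predicts zero biomass and the slope β is numerically a
volumetric biomass density (g m⁻³). Model quality is reported as the
no-intercept adjusted R² (uncentred total sum of squares) and a
leave-one-out cross-validation error computed exactly via the leverage
identity e&#7522;/(1 − ℓ&#7522;), ℓ&#7522; = h&#7522;²/Σh², expressed relative to mean predicted
biomass.

Because SfM reconstructions degrade when foliage moves between image
captures, survey covariates are tested with mixed models of biomass on
height with a height × covariate interaction and a random per-PFT height
slope: a gamma-identity GLMM for wind speed (fitted by Gauss–Hermite
maximum likelihood) and Gaussian LMMs for sun elevation (clear-sky plots,
sky codes ≤ 5) and binary cloud cover (sky codes ≥ 6). A positive
height × wind interaction means windier surveys reconstruct systematically
shorter canopies.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
survey (36 plots, six plant functional types, ~5 mm sampling, 1 cm vertical
noise, 20% biomass CV, surveyed at 1.5 m s⁻¹ wind):

```bash
python analysis/01_simulate_scenes.py
python analysis/02_extract_canopy_metrics.py
python analysis/03_fit_allometry.py
python analysis/04_environmental_effects.py
```

which prints (abridged):

```
extracted metrics for 36/36 plots -> results/plot_metrics.csv
mean height bias vs truth: -0.0197 m (vertical noise 0.01 m, wind 1.5 m/s at k=0.05)

pft-level models (6 fitted, 0 skipped) -> results/allometry_pft.csv
    group  n  slope_g_m3  adj_r2  loocv_pct
     fern  6      1042.0    0.99       13.6
     forb  6      1181.0    0.99       14.8
graminoid  6      3009.0    0.98       22.0
    shrub  6      3042.0    0.97       17.7
     tree  6      4759.0    0.96       29.6
succulent  6     11517.0    0.95       35.2

 wind model [gamma_glmm_gh] height x wind: +110.1 +- 17.1 (p = 1.1e-10)
  sun model [gaussian_lmm] height x sun: -2.7 +- 6.0 (p = 0.67)
cloud model [gaussian_lmm] height x cloudy: -126.9 +- 182.1 (p = 0.51)
```

The fitted slopes are the recovered volumetric densities: with only six
noisy plots per group they sit within ~5% of the generative values for
most PFTs (the tree group, with the fewest points per crown, is worst at
−15%), and the wind model recovers the injected positive interaction while
sun and cloud — generated with no effect — test as null. The same pipeline
is exposed as a CLI (`canopymass simulate|metrics|allometry|effects|
pipeline`) driven by a YAML config.

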