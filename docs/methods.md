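# Methods

## Scope and data model

The package analyses finished photogrammetric point clouds; image
acquisition and structure-from-motion reconstruction are upstream. Inputs
are (a) a vegetation point cloud in a planar metric CRS with an optional
per-point noise classification (LAS classes 7/18, a PLY `noise` property,
or a CSV column) for plot infrastructure that must be excluded, and (b) a
plot table with ≥3 ordered corner coordinates including surveyed ground
elevation, dry biomass (g), taxon, plant functional type (PFT: fern, forb,
graminoid, shrub, tree, succulent), and survey covariates (wind speed at
~2 m, timestamp + latitude/longitude for sun elevation, an ordinal 0–10
sky code). Plot area comes from the shoelace formula on the corner
polygon; a bounding box under 0.5 × 0.5 m (the field-protocol minimum)
warns but does not error.

## Terrain

The digital terrain model is a TIN: a Delaunay triangulation of the plot
corners' planar projections with the surveyed elevation carried per
vertex, queried by barycentric-linear interpolation. By default one TIN is
built per survey from the union of all plot corners, so plot interiors
gain support from neighbouring corners; a per-plot mode exists for
isolated plots. Input points are sorted before triangulation so
co-circular ties break identically regardless of input order; duplicate
planar locations with equal elevation (shared corners of adjacent plots)
merge silently, conflicting elevations are an error. Queries outside the
convex hull raise by default; an opt-in fallback extends the nearest
triangle's plane, since corners define the hull and interior points should
always be covered. Linear reproduction of affine surfaces is exact to
≤1e-9 m (verified), and interpolated values are bounded by the containing
triangle's vertex elevations.

## Canopy height metrics

Per plot: clip (boundary-inclusive point-in-polygon — surveyed corners
delimit and belong to the plot; excluding boundary points would bias small
plots), subtract the TIN elevation, clamp negative heights to zero
(points reconstructed below the terrain are artefacts), rasterize at
0.01 m taking the per-cell maximum with half-open cell intervals (points
on the bounding box's top/right edge fold into the last cell so nothing is
lost), fill empty cells by a single-pass IDW over the centred 7 × 7 window
with power 1 — only pre-fill populated cells serve as sources, the centre
cell is excluded, distances are cell-centre to cell-centre, and cells with
no populated cell in the window remain empty — then summarize. All
constants are configurable (`ChmConfig`) with these defaults.

The plot mean is taken over populated cells only: unfilled cells represent
unobserved, not zero, canopy. The alternative zero-fill policy is
available for sensitivity analysis. Maximum height is the maximum grid
cell (identical to the highest point whenever that point survives
gridding). A plot with no in-polygon points, or no populated cells, is an
"unreconstructed plot" signal that callers report rather than an abort —
mirroring how real surveys lose some plots.

## Allometry

Through-origin OLS of biomass per area on mean canopy height: β̂ = Σhb/Σh²,
residual SE with n − 1 df, slope SE = resid_se/√Σh², two-sided t test.
"Adjusted R²" follows the no-intercept convention of mainstream regression
software: uncentred total sum of squares Σb²/n with the df correction.
A centred variant is available by flag; the two are not comparable and the
uncentred one is the default reported.

LOOCV uses the exact leverage identity for linear smoothers
(e&#7522;/(1 − ℓ&#7522;), ℓ&#7522; = h&#7522;²/Σh²), verified against an explicit refit loop
kept in the code base as the reference path. The out-of-sample errors are
aggregated as RMSE (MAE available). Normalisation: dividing a g m⁻² error
by the slope (g m⁻³) yields metres; to express a percentage the package
additionally divides by the group mean height — equivalently, RMSE
relative to mean predicted biomass. Both the metre value and the
percentage are reported, since reasonable alternative definitions of a
"relative LOOCV error" exist.

Group models are fitted per species or per PFT for groups with ≥4 plots
(smaller groups are listed as skipped), ordered by ascending slope.

## Environmental-effect models

All three models share the fixed-effect structure intercept + height +
covariate + height × covariate and a random height slope per PFT with no
random intercept — PFTs differ primarily in volumetric density, i.e. in
slope, and a random intercept would contradict the zero-height/zero-biomass
constraint. The interaction is the quantity of interest: a positive
height × wind coefficient means biomass per unit reconstructed height
rises with wind, i.e. windier surveys reconstruct shorter canopies.

**Wind** uses a gamma error distribution with an identity link (biomass is
positive and right-skewed with roughly constant CV, and the mean model
stays linear in height). No gamma-family mixed model with a random slope
exists in the scientific Python stack, so the model is fitted by direct
maximum likelihood: the one-dimensional per-PFT random slope is integrated
out by Gauss–Hermite quadrature (30 nodes), the marginal likelihood
maximised by Nelder–Mead followed by BFGS, and Wald SEs taken from a
central-difference Hessian. Zero responses are inadmissible under a gamma
family and are shifted by half the smallest positive response with a
warning. Succulents are excluded by default (an order-of-magnitude denser
PFT that destabilises convergence). If the fit fails (non-finite
likelihood or a non-positive-definite Hessian) the model falls back,
flagged in the output, to a Gaussian LMM with the same fixed effects,
which preserves the sign test.

**Sun** (restricted to clear-sky plots, sky codes ≤ 5) and **cloud**
(binary factor, sky codes ≥ 6; group sizes are reported because imbalanced
designs make the contrast unreliable) use Gaussian linear mixed models via
REML (statsmodels MixedLM).

Inference convention for the Gaussian LMMs: covariates recorded once per
survey are replicated at the survey level, not the plot level, so their
terms (covariate main effect and interaction) are tested against a t
reference with containment degrees of freedom — the number of distinct
surveys minus the number of survey-level parameters — rather than a normal
reference; plot-level terms use residual df. This is the nlme convention
and the classic guard against pseudo-replication when surveys are few; in
null simulations under the generator's multiplicative biomass noise it
brings the interaction test's size to ≈4–8% at nominal 5%, where a normal
reference was anticonservative (~17%).

Sun elevation is computed from a standard low-precision solar ephemeris
(geometric mean longitude/anomaly, equation of centre, apparent longitude,
obliquity, equation of time, hour angle) with the usual refraction
polynomial — accurate to ~0.2° in recent decades, ample for a survey
covariate.

Downstream reporting: per-group slopes are tabulated against a covariate
with ±83% normal confidence intervals (z ≈ 1.372; non-overlap of two 83%
intervals approximates a 5% pairwise test), and fitted models generate
predicted biomass-vs-height curves at chosen covariate levels, marginal
over the random effects, with 95% bands from the fixed-effect covariance
and an explicit extrapolation warning outside the fitted covariate range.

## Synthetic surveys

The generator inverts the analysis assumptions so recovery is testable
end to end. Per plot, a true canopy field h\*(x, y) ≥ 0 is drawn — a
smooth positive random field (random-cosine spectrum, configurable
roughness and 0.25 m correlation length) for swards, or an upper envelope
of ellipsoidal crown caps — with the plot-mean level drawn uniformly from
0.05–1.5 m, matching the range of mean canopy heights such surveys
encounter. Biomass per area is b = ρ·h̄\*·exp(δ − σ²/2) with ρ the PFT
volumetric density and δ lognormal with CV 0.2, so E[b] = ρ·h̄\* and the
through-origin slope is unbiased by construction; zero height gives zero
biomass exactly. Default densities (g m⁻³): fern 1096, forb 1191,
graminoid 2898, shrub 3214, tree 5572, succulent 11 532.

The point cloud samples the field uniformly at 40 000 points m⁻² (~5 mm
ground sampling; Poisson count, optional dropout), with vertical Gaussian
noise of 0.01 m (~2 pixels at 5 mm GSD) and a floor at the terrain. Wind
enters as per-point multiplicative height loss h\*·(1 − k·w·U) with
U ~ Uniform(0, 1): non-concurrent image capture of moving foliage loses
matched canopy-top points heterogeneously, so a rigid displacement would
be the wrong model. Plots are laid out on a grid with 1 m spacing; corners
take exact terrain elevations with optional ±0.03 m GNSS noise. All
randomness flows from one seed; identical parameters reproduce the scene
byte for byte.

A companion observation-level generator draws (h̄ reconstructed, b) pairs
directly — with the deterministic attenuation factor (1 − k·w) and 0.01 m
height measurement noise — for mixed-model calibration studies where the
point-cloud stage would add nothing but runtime.

What the generator does **not** emulate: occlusion and view-geometry
effects, radiometry and shadows, spatially correlated reconstruction
error, species mixtures within a plot, and terrain error inside plots
(corners sit exactly on the generating surface unless noise is added).
Passing recovery tests therefore demonstrate correctness of the analysis
chain under its own assumptions, not field accuracy of photogrammetry.

## Numerical and design notes

* Per-cell **max** gridding interacts with the wind model: the maximum
  over m points in a cell keeps the least-attenuated point
  (E[min U] = 1/(m+1)), so dense sampling dilutes the per-point
  attenuation. Effect-direction experiments therefore sample near 1 point
  per cell (10 000 m⁻² at 0.01 m) so the attenuation survives gridding.
* Recovery experiments use constant swards (roughness 0): with a rough
  field the cell-max estimator is biased high by O(|∇h|·cell), which is a
  property of the method, not an implementation error; the
  resolution-refinement test shows the bias shrink as cells refine.
* LAS output uses a dynamic coordinate scale (offset at the minimum
  corner, scale ≥ 1e-7 m) so round-trips are faithful to 1e-6 m at site
  extents; LAZ is not handled (decompress first). GeoTIFF georeferencing
  uses ModelPixelScale/ModelTiepoint plus the GDAL nodata tag (−9999).
* Problem sizes in tests and the acceptance script (30 plots/PFT at
  0.5 m plots for pipeline recovery; 300 plots × 100 replicates at the
  observation level for null calibration) were chosen as the smallest
  designs that make the respective checks sharp; the full-scene route at
  those replicate counts would add only runtime.
* Pipeline outputs are a pure function of (inputs, config, seed); each
  stage logs one structured line (stage, counts, parameters) so every
  filter is auditable.

## Known limitations

The gamma GLMM's quadrature assumes a single random-slope dimension;
nested (species-within-PFT) or crossed random effects are out of scope.
The identity link admits negative mean predictions far outside the data
range — guarded during fitting, but extrapolated effect curves can cross
zero. LOOCV percentages depend on the chosen normaliser (documented
above) and on how many surveys a group spans, so they should be compared
across groups with care. Sky codes are treated as an opaque ordinal with
the single ≥6 threshold; no geodetic reprojection is performed, and all
inputs must share one planar CRS.
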