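"""Wind, sun-elevation and cloud effects on the height-biomass relation.

Photogrammetric canopy heights are reconstruction artefacts as much as
measurements: foliage moving in wind between non-concurrent image captures
degrades tie-point matching at the canopy top and lowers the reconstructed
surface, while illumination (sun elevation, cloud) changes shadow structure.
These survey-level covariates are tested by mixed models of per-area biomass
on reconstructed mean height with a height x covariate interaction as the
quantity of interest, and plant functional type (PFT) as a random effect on
the height slope (PFTs differ primarily in volumetric density, i.e. slope):

* wind      — gamma error, identity link (biomass is positive, right-skewed,
              and the mean model stays linear in height); succulents are
              excluded before fitting;
* sun       — Gaussian linear mixed model on clear-sky plots (sky code <= 5);
* cloud     — Gaussian linear mixed model with a binary cloudy factor
              (sky code >= 6).

No off-the-shelf gamma-family mixed model with a random slope exists in the
scientific Python stack, so the wind model is fitted here by direct maximum
likelihood: the per-PFT random slope is integrated out with one-dimensional
Gauss-Hermite quadrature and the marginal likelihood maximised numerically.
If that fit fails to converge the model falls back — flagged, never
silently — to a Gaussian linear mixed model with the same fixed effects,
which preserves the sign test on the interaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

__all__ = [
    "EffectFit", "compute_sun_elevation", "fit_wind_model", "fit_sun_model",
    "fit_cloud_model", "slope_vs_covariate", "simulate_effect_curves",
    "CLOUDY_SKY_CODE",
]

CLOUDY_SKY_CODE = 6  # sky codes >= 6: sun obscured


# ------------------------------------------------------------ solar geometry

def _julian_century(when: datetime) -> float:
    if when.tzinfo is None:
        when = when.replace(tzinfo=timezone.utc)
    jd = when.timestamp() / 86400.0 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def compute_sun_elevation(latitude: float, longitude: float,
                          when) -> float:
    """Apparent solar elevation (degrees above horizon) at a place and time.

    Standard low-precision solar ephemeris (geometric mean longitude and
    anomaly, equation of centre, apparent longitude, obliquity, equation of
    time, hour angle) with the usual atmospheric refraction correction;
    accurate to about 0.2 degrees for recent decades, well inside the 0.5
    degree tolerance that matters for survey covariates.  ``when`` is a
    timezone-aware datetime or ISO 8601 string; naive times are taken as UTC.
    """
    if isinstance(when, str):
        when = datetime.fromisoformat(when.replace("Z", "+00:00"))
    if isinstance(when, pd.Timestamp):
        when = when.to_pydatetime()
    if when.tzinfo is None:
        when = when.replace(tzinfo=timezone.utc)
    when = when.astimezone(timezone.utc)
    jc = _julian_century(when)
    rad = math.radians
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        math.sin(rad(m)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(rad(2 * m)) * (0.019993 - 0.000101 * jc)
        + math.sin(rad(3 * m)) * 0.000289
    )
    true_long = l0 + ctr
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(rad(omega))
    mean_obliq = 23.0 + (26.0 + (
        21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))
    ) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(rad(omega))
    decl = math.degrees(
        math.asin(math.sin(rad(obliq)) * math.sin(rad(app_long)))
    )
    vary = math.tan(rad(obliq / 2.0)) ** 2
    eqtime = 4.0 * math.degrees(
        vary * math.sin(2 * rad(l0))
        - 2 * ecc * math.sin(rad(m))
        + 4 * ecc * vary * math.sin(rad(m)) * math.cos(2 * rad(l0))
        - 0.5 * vary * vary * math.sin(4 * rad(l0))
        - 1.25 * ecc * ecc * math.sin(2 * rad(m))
    )
    minutes = (when.hour * 60 + when.minute + when.second / 60.0
               + when.microsecond / 6e7)
    tst = (minutes + eqtime + 4.0 * longitude) % 1440.0
    ha = tst / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0
    cos_zen = (
        math.sin(rad(latitude)) * math.sin(rad(decl))
        + math.cos(rad(latitude)) * math.cos(rad(decl)) * math.cos(rad(ha))
    )
    zen = math.degrees(math.acos(min(1.0, max(-1.0, cos_zen))))
    elev = 90.0 - zen
    return elev + _refraction_deg(elev)


def _refraction_deg(elev: float) -> float:
    if elev > 85.0:
        return 0.0
    te = math.tan(math.radians(elev))
    if elev > 5.0:
        sec = 58.1 / te - 0.07 / te**3 + 0.000086 / te**5
    elif elev > -0.575:
        sec = 1735.0 + elev * (
            -518.2 + elev * (103.4 + elev * (-12.79 + elev * 0.711))
        )
    else:
        sec = -20.772 / te
    return sec / 3600.0


# ------------------------------------------------------------ effect fits

@dataclass
class EffectFit:
    """A fitted survey-covariate model and what downstream plotting needs."""

    response: str
    covariate: str
    family: str                      # "gamma_glmm" | "gaussian_lmm"
    method: str                      # estimation route actually used
    terms: list[str]
    coef: pd.DataFrame               # term, estimate, se, stat, p
    cov_fixed: np.ndarray            # covariance of fixed effects
    converged: bool
    sigma_b: float                   # SD of random height slope across PFTs
    extra: dict = field(default_factory=dict)
    covariate_range: tuple[float, float] = (np.nan, np.nan)
    height_range: tuple[float, float] = (np.nan, np.nan)
    group_sizes: dict = field(default_factory=dict)

    @property
    def interaction(self) -> pd.Series:
        return self.coef.set_index("term").loc[f"height:{self.covariate}"]

    def params(self) -> np.ndarray:
        return self.coef["estimate"].to_numpy()


def _design(h: np.ndarray, w: np.ndarray, covariate: str):
    X = np.column_stack([np.ones_like(h), h, w, h * w])
    terms = ["intercept", "height", covariate, f"height:{covariate}"]
    return X, terms


def _positive_response(y: np.ndarray) -> np.ndarray:
    """Shift exact zeros for gamma-family fitting (support is y > 0)."""
    if (y < 0).any():
        raise ValueError("negative biomass response")
    if (y == 0).any():
        pos = y[y > 0]
        if pos.size == 0:
            raise ValueError("all responses zero; gamma model undefined")
        shift = 0.5 * pos.min()
        warnings.warn(
            f"{int((y == 0).sum())} zero response(s) shifted by {shift:.4g} "
            "for the gamma family", stacklevel=3,
        )
        y = np.where(y == 0, shift, y)
    return y


def _gamma_glmm_nll(theta, y, X, h, group_idx, n_groups, gh_x, gh_w):
    beta = theta[:-2]
    sigma_b = np.exp(theta[-2])
    shape = np.exp(theta[-1])
    eta = X @ beta
    nodes = math.sqrt(2.0) * sigma_b * gh_x          # (K,)
    # mu for every observation at every node: (n, K)
    mu = eta[:, None] + h[:, None] * nodes[None, :]
    bad = mu <= 1e-10
    mu = np.where(bad, 1e-10, mu)
    logpdf = (
        shape * (np.log(shape) - np.log(mu))
        - special.gammaln(shape)
        + (shape - 1.0) * np.log(y)[:, None]
        - shape * y[:, None] / mu
    )
    logpdf = np.where(bad, -1e6, logpdf)
    # per-group, per-node sums of log densities
    grp = np.zeros((n_groups, len(gh_x)))
    np.add.at(grp, group_idx, logpdf)
    log_w = np.log(gh_w / math.sqrt(math.pi))
    ll = special.logsumexp(grp + log_w[None, :], axis=1).sum()
    return -ll


def _numeric_hessian(fun, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                4.0 * steps[i] * steps[j]
            )
    return H


def _fit_gamma_glmm(y, X, h, groups, terms, covariate, gh_points=30):
    labels, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(labels)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(gh_points)
    # starting values: plain OLS betas, moment estimate of the gamma shape
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu0 = np.maximum(X @ beta0, 1e-6)
    cv2 = max(np.mean(((y - mu0) / mu0) ** 2), 1e-3)
    theta0 = np.concatenate([
        beta0,
        [np.log(max(0.1 * abs(beta0[1]) + 1e-3, 1e-3))],
        [np.log(1.0 / cv2)],
    ])
    args = (y, X, h, group_idx, n_groups, gh_x, gh_w)
    with np.errstate(all="ignore"):
        res = optimize.minimize(
            _gamma_glmm_nll, theta0, args=args, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-6},
        )
        res = optimize.minimize(
            _gamma_glmm_nll, res.x, args=args, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-5},
        )
        H = _numeric_hessian(lambda t: _gamma_glmm_nll(t, *args), res.x)
    k = X.shape[1]
    try:
        cov_all = np.linalg.inv(H)
        cov_fixed = cov_all[:k, :k]
        se = np.sqrt(np.diag(cov_fixed))
        ok = np.isfinite(se).all() and (np.diag(cov_fixed) > 0).all()
    except np.linalg.LinAlgError:
        cov_fixed = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        ok = False
    converged = bool(np.isfinite(res.fun)) and ok
    beta = res.x[:k]
    z = beta / se
    coef = pd.DataFrame({
        "term": terms, "estimate": beta, "se": se, "stat": z,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    })
    return coef, cov_fixed, converged, {
        "sigma_b": float(np.exp(res.x[-2])),
        "shape": float(np.exp(res.x[-1])),
        "loglik": float(-res.fun),
        "n_groups": n_groups,
    }


def _fit_gaussian_lmm(y, X, h, groups, terms, n_clusters=None):
    """REML linear mixed model with a random height slope per PFT.

    Survey-level terms (the covariate main effect and the height x
    covariate interaction) are tested against a t reference with
    containment degrees of freedom — the number of distinct surveys minus
    the number of survey-level parameters — because a covariate recorded
    once per survey is replicated at the survey level, not the plot level
    (the nlme convention; guards against pseudo-replication when surveys
    are few).  Plot-level terms use residual df.
    """
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog=y, exog=X, groups=groups,
                           exog_re=h.reshape(-1, 1))
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
    if fit is None:
        raise ValueError("linear mixed model failed to fit")
    k = X.shape[1]
    n = len(y)
    beta = np.asarray(fit.fe_params)
    cov_fixed = np.asarray(fit.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov_fixed))
    tval = beta / se
    df = np.full(k, max(n - k, 1), dtype=float)
    if n_clusters is not None:
        df[2:] = max(n_clusters - 2, 3)
    coef = pd.DataFrame({
        "term": terms, "estimate": beta, "se": se, "stat": tval,
        "p": 2.0 * stats.t.sf(np.abs(tval), df), "df": df,
    })
    sigma_b = float(np.sqrt(max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)))
    return coef, cov_fixed, bool(fit.converged), {
        "sigma_b": sigma_b, "scale": float(fit.scale),
    }


def _prepare(df: pd.DataFrame, covariate_col: str, covariate: str,
             drop_pfts=()):
    need = {"biomass_g_m2", "mean_height_m", "pft", covariate_col}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"observations lack columns {sorted(missing)}")
    df = df.dropna(subset=list(need))
    if drop_pfts:
        dropped = df["pft"].isin(drop_pfts)
        if dropped.any():
            warnings.warn(
                f"excluding {int(dropped.sum())} plot(s) of PFT(s) "
                f"{sorted(set(df.loc[dropped, 'pft']))} from the "
                f"{covariate} model", stacklevel=3,
            )
        df = df[~dropped]
    if df["pft"].nunique() < 2:
        raise ValueError(f"{covariate} model needs >=2 PFTs")
    if df[covariate_col].nunique() < 2:
        raise ValueError(
            f"{covariate} model needs >=2 distinct values of "
            f"{covariate_col} (covariate not estimable)"
        )
    return df


def fit_wind_model(obs: pd.DataFrame, exclude_pfts=("succulent",),
                   gh_points: int = 30) -> EffectFit:
    """Gamma-identity mixed model of biomass on height x wind speed.

    ``obs`` needs columns ``biomass_g_m2``, ``mean_height_m``,
    ``wind_speed_ms`` and ``pft``.  The headline output is the sign and
    significance of the height:wind interaction — positive means biomass per
    unit reconstructed height rises with wind, i.e. windier surveys
    reconstruct systematically shorter canopies.
    """
    df = _prepare(obs, "wind_speed_ms", "wind", drop_pfts=exclude_pfts)
    y = _positive_response(df["biomass_g_m2"].to_numpy(float))
    h = df["mean_height_m"].to_numpy(float)
    w = df["wind_speed_ms"].to_numpy(float)
    X, terms = _design(h, w, "wind")
    groups = df["pft"].to_numpy()
    coef, cov, converged, extra = _fit_gamma_glmm(
        y, X, h, groups, terms, "wind", gh_points=gh_points
    )
    method = "gamma_glmm_gh"
    if not converged:
        warnings.warn(
            "gamma GLMM did not converge; falling back to a Gaussian LMM "
            "with the same fixed effects (flagged)", stacklevel=2,
        )
        n_clusters = (df["survey_id"].nunique()
                      if "survey_id" in df.columns else None)
        coef, cov, converged, extra = _fit_gaussian_lmm(
            y, X, h, groups, terms, n_clusters=n_clusters
        )
        method = "gaussian_lmm_fallback"
    return EffectFit(
        response="biomass_g_m2", covariate="wind", family="gamma_glmm",
        method=method, terms=terms, coef=coef, cov_fixed=cov,
        converged=converged, sigma_b=extra.get("sigma_b", np.nan),
        extra=extra, covariate_range=(float(w.min()), float(w.max())),
        height_range=(float(h.min()), float(h.max())),
        group_sizes=df["pft"].value_counts().to_dict(),
    )


def fit_sun_model(obs: pd.DataFrame, max_sky_code: int = 5) -> EffectFit:
    """Gaussian LMM of biomass on height x sun elevation, clear skies only."""
    if "sky_code" in obs.columns:
        obs = obs[obs["sky_code"] <= max_sky_code]
    if len(obs) == 0:
        raise ValueError(
            f"no observations with sky_code <= {max_sky_code}"
        )
    df = _prepare(obs, "sun_elevation_deg", "sun")
    y = df["biomass_g_m2"].to_numpy(float)
    h = df["mean_height_m"].to_numpy(float)
    s = df["sun_elevation_deg"].to_numpy(float)
    X, terms = _design(h, s, "sun")
    n_clusters = (df["survey_id"].nunique() if "survey_id" in df.columns
                  else df["sun_elevation_deg"].nunique())
    coef, cov, converged, extra = _fit_gaussian_lmm(
        y, X, h, df["pft"].to_numpy(), terms, n_clusters=n_clusters
    )
    return EffectFit(
        response="biomass_g_m2", covariate="sun", family="gaussian_lmm",
        method="gaussian_lmm", terms=terms, coef=coef, cov_fixed=cov,
        converged=converged, sigma_b=extra.get("sigma_b", np.nan),
        extra=extra, covariate_range=(float(s.min()), float(s.max())),
        height_range=(float(h.min()), float(h.max())),
        group_sizes=df["pft"].value_counts().to_dict(),
    )


def fit_cloud_model(obs: pd.DataFrame) -> EffectFit:
    """Gaussian LMM with a binary cloudy factor (sky code >= 6).

    The returned fit records the clear/cloudy group sizes; strongly
    imbalanced designs make the cloud contrast unreliable and downstream
    reporting carries that caveat.
    """
    if "cloudy" not in obs.columns:
        if "sky_code" not in obs.columns:
            raise ValueError("need a 'cloudy' or 'sky_code' column")
        obs = obs.assign(cloudy=obs["sky_code"] >= CLOUDY_SKY_CODE)
    levels = obs["cloudy"].nunique()
    if levels < 2:
        raise ValueError(
            "cloud model needs both clear and cloudy observations"
        )
    df = _prepare(obs, "cloudy", "cloudy")
    y = df["biomass_g_m2"].to_numpy(float)
    h = df["mean_height_m"].to_numpy(float)
    c = df["cloudy"].to_numpy(float)
    X, terms = _design(h, c, "cloudy")
    n_clusters = (df["survey_id"].nunique() if "survey_id" in df.columns
                  else 2)
    coef, cov, converged, extra = _fit_gaussian_lmm(
        y, X, h, df["pft"].to_numpy(), terms, n_clusters=n_clusters
    )
    sizes = {"clear": int((c == 0).sum()), "cloudy": int((c == 1).sum())}
    return EffectFit(
        response="biomass_g_m2", covariate="cloudy", family="gaussian_lmm",
        method="gaussian_lmm", terms=terms, coef=coef, cov_fixed=cov,
        converged=converged, sigma_b=extra.get("sigma_b", np.nan),
        extra=extra, covariate_range=(0.0, 1.0),
        height_range=(float(h.min()), float(h.max())),
        group_sizes=sizes,
    )


def slope_vs_covariate(models: pd.DataFrame, covariate: str,
                       ci_level: float = 0.83) -> pd.DataFrame:
    """Per-group slopes against a survey covariate with normal CIs.

    ``models`` needs columns ``group``, the covariate, ``slope_g_m3`` and
    ``slope_se_g_m3``; rows lacking a standard error are skipped with a
    warning.  The 83% default makes non-overlap of two intervals roughly a
    5% pairwise test.
    """
    if not 0 <= ci_level < 1:
        raise ValueError("ci_level must be in [0, 1)")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    for _, row in models.iterrows():
        se = row.get("slope_se_g_m3", np.nan)
        if not np.isfinite(se):
            warnings.warn(
                f"group {row.get('group')!r}: missing slope SE, skipped",
                stacklevel=2,
            )
            continue
        slope = row["slope_g_m3"]
        rows.append({
            "group": row["group"], covariate: row[covariate],
            "slope_g_m3": slope, "ci_lo": slope - z * se,
            "ci_hi": slope + z * se,
        })
    return pd.DataFrame(rows)


def simulate_effect_curves(fit: EffectFit, covariate_levels,
                           height_grid) -> pd.DataFrame:
    """Predicted biomass over a height grid at chosen covariate levels.

    Predictions are marginal over the random PFT slope (random effect at
    its zero mean) with 95% normal confidence bands from the fixed-effect
    covariance.  Levels outside the fitted covariate range are returned with
    an extrapolation warning.
    """
    if not fit.converged:
        raise ValueError("cannot simulate curves from a non-converged fit")
    h = np.asarray(height_grid, dtype=float)
    beta = fit.params()
    lo, hi = fit.covariate_range
    rows = []
    for level in covariate_levels:
        if np.isfinite(lo) and not (lo <= level <= hi):
            warnings.warn(
                f"covariate level {level} outside fitted range "
                f"[{lo:.3g}, {hi:.3g}]: extrapolating", stacklevel=2,
            )
        X = np.column_stack(
            [np.ones_like(h), h, np.full_like(h, level), h * level]
        )
        mu = X @ beta
        var = np.einsum("ij,jk,ik->i", X, fit.cov_fixed, X)
        half = 1.959963984540054 * np.sqrt(np.maximum(var, 0.0))
        for hh, m, d in zip(h, mu, half):
            rows.append({
                fit.covariate: level, "mean_height_m": hh,
                "predicted_g_m2": m, "ci_lo": m - d, "ci_hi": m + d,
            })
    return pd.DataFrame(rows)
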