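"""Zero-intercept height-biomass allometry with leave-one-out validation.

The allometric model is ordinary least squares through the origin,

    b_i = beta * h_i + e_i,

with b aboveground dry biomass per ground area (g m^-2) and h plot mean
canopy height (m).  Constraining the intercept to zero encodes the physical
requirement that zero canopy height predicts zero biomass, and makes the
slope beta numerically equal to a volumetric biomass density in g m^-3.

Closed forms used throughout (through-origin OLS, n observations, 1 model
degree of freedom):

    beta      = sum(h b) / sum(h^2)
    resid_se  = sqrt(RSS / (n - 1))
    se(beta)  = resid_se / sqrt(sum(h^2))
    t         = beta / se(beta),  n - 1 df, two-sided p
    adj R^2   = 1 - [RSS / (n - 1)] / [sum(b^2) / n]   (uncentered total SS,
                the no-intercept convention of mainstream regression software)

Leave-one-out cross-validation uses the exact leverage identity for linear
smoothers: the out-of-sample residual for observation i is e_i / (1 - l_i)
with leverage l_i = h_i^2 / sum(h^2), so no refitting loop is needed.  The
reported LOOCV % is the root-mean-square of those residuals expressed
relative to the mean predicted biomass, 100 * RMSE / (beta * mean(h)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometricModel", "fit_zero_intercept", "loocv_relative_error",
    "fit_group_models",
]


@dataclass(frozen=True)
class AllometricModel:
    group: str
    n: int
    n_surveys: int
    slope: float          # g m^-2 per m of mean height == g m^-3
    slope_se: float
    resid_se: float       # g m^-2
    adj_r2: float
    t_stat: float
    p_value: float
    loocv_pct: float      # %
    loocv_rmse_m: float   # LOOCV error divided by the slope, in metres

    def ci(self, level: float = 0.83) -> tuple[float, float]:
        """Normal-approximation confidence interval on the slope."""
        if not 0 <= level < 1:
            raise ValueError("level must be in [0, 1)")
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.slope - z * self.slope_se, self.slope + z * self.slope_se


def _as_hb(obs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obs, pd.DataFrame):
        h = obs["mean_height_m"].to_numpy(float)
        b = obs["biomass_g_m2"].to_numpy(float)
    else:
        h, b = obs
        h = np.asarray(h, dtype=float)
        b = np.asarray(b, dtype=float)
    if h.shape != b.shape:
        raise ValueError("height and biomass vectors differ in length")
    if not (np.isfinite(h).all() and np.isfinite(b).all()):
        raise ValueError("non-finite height or biomass observation")
    if (h < 0).any() or (b < 0).any():
        raise ValueError("negative height or biomass observation")
    return h, b


def fit_zero_intercept(obs, group: str = "", n_surveys: int = 0,
                       centered_r2: bool = False) -> AllometricModel:
    """Fit b = beta*h through the origin with full diagnostics.

    ``obs`` is either a DataFrame with columns ``mean_height_m`` and
    ``biomass_g_m2`` or an ``(h, b)`` pair of vectors.
    """
    h, b = _as_hb(obs)
    n = len(h)
    if n < 2:
        raise ValueError(f"group {group!r}: need >=2 observations, got {n}")
    shh = float(np.dot(h, h))
    if shh == 0.0:
        raise ValueError(f"group {group!r}: all heights are zero; "
                         "slope is unidentifiable")
    beta = float(np.dot(h, b)) / shh
    resid = b - beta * h
    rss = float(np.dot(resid, resid))
    df = n - 1
    resid_se = np.sqrt(rss / df)
    slope_se = resid_se / np.sqrt(shh)
    if slope_se > 0:
        t = beta / slope_se
        p = 2.0 * stats.t.sf(abs(t), df)
    else:  # perfect fit
        t, p = np.inf, 0.0
    if centered_r2:
        tss = float(np.sum((b - b.mean()) ** 2)) / max(n - 1, 1)
    else:
        tss = float(np.dot(b, b)) / n
    adj_r2 = 1.0 - (rss / df) / tss if tss > 0 else 1.0
    loocv_pct, loocv_m = loocv_relative_error((h, b), _beta=beta)
    return AllometricModel(
        group=group, n=n, n_surveys=n_surveys, slope=beta,
        slope_se=float(slope_se), resid_se=float(resid_se),
        adj_r2=float(adj_r2), t_stat=float(t), p_value=float(p),
        loocv_pct=float(loocv_pct), loocv_rmse_m=float(loocv_m),
    )


def loocv_relative_error(obs, aggregate: str = "rmse",
                         _beta: float | None = None
                         ) -> tuple[float, float]:
    """Leave-one-out prediction error of the through-origin fit.

    Returns ``(percent, metres)``: the aggregated out-of-sample error as a
    percentage of mean predicted biomass, and the same error divided by the
    slope alone (units of metres of canopy height).  ``aggregate`` is
    ``"rmse"`` (default) or ``"mae"``.

    Observations with leverage 1 (a single plot carrying all of sum(h^2))
    cannot be predicted out-of-sample and are excluded with a warning.
    """
    h, b = _as_hb(obs)
    n = len(h)
    if n < 3:
        raise ValueError(f"LOOCV needs >=3 observations, got {n}")
    shh = float(np.dot(h, h))
    if shh == 0.0:
        raise ValueError("all heights zero; LOOCV undefined")
    beta = float(np.dot(h, b)) / shh if _beta is None else _beta
    leverage = h * h / shh
    resid = b - beta * h
    ok = leverage < 1.0 - 1e-12
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} observation(s) with leverage 1 excluded "
            "from LOOCV", stacklevel=2,
        )
    loo = resid[ok] / (1.0 - leverage[ok])
    if loo.size == 0:
        raise ValueError("no observations with leverage < 1")
    if aggregate == "rmse":
        err = float(np.sqrt(np.mean(loo ** 2)))
    elif aggregate == "mae":
        err = float(np.mean(np.abs(loo)))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    err_m = err / beta if beta > 0 else np.nan
    mean_pred = beta * float(h.mean())
    pct = 100.0 * err / mean_pred if mean_pred > 0 else np.nan
    return pct, err_m


def loocv_refit_loop(obs) -> np.ndarray:
    """Out-of-sample LOOCV residuals by explicit refitting (reference path).

    Kept as the slow, obviously-correct counterpart of the leverage
    shortcut used by :func:`loocv_relative_error`.
    """
    h, b = _as_hb(obs)
    n = len(h)
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        shh = float(np.dot(h[mask], h[mask]))
        beta_i = float(np.dot(h[mask], b[mask])) / shh
        out[i] = b[i] - beta_i * h[i]
    return out


def fit_group_models(obs: pd.DataFrame, grouping: str = "species",
                     min_n: int = 4,
                     centered_r2: bool = False) -> pd.DataFrame:
    """One through-origin model per group with at least ``min_n`` plots.

    ``obs`` needs columns ``mean_height_m``, ``biomass_g_m2``, ``survey_id``
    and the grouping column (``species`` or ``pft``).  Returns a table
    ordered by ascending slope; groups below the threshold appear with
    ``skipped = True`` and no fit statistics.
    """
    if len(obs) == 0:
        raise ValueError("no observations to fit")
    if grouping not in obs.columns:
        raise ValueError(f"grouping column {grouping!r} missing")
    rows = []
    for label, grp in obs.groupby(grouping, sort=True):
        if len(grp) < max(min_n, 2):  # slope needs >=2 points regardless
            rows.append({"group": label, "n": len(grp), "skipped": True})
            continue
        n_surveys = grp["survey_id"].nunique() if "survey_id" in grp else 0
        m = fit_zero_intercept(grp, group=str(label), n_surveys=n_surveys,
                               centered_r2=centered_r2)
        rows.append({
            "group": m.group, "n": m.n, "n_surveys": m.n_surveys,
            "slope_g_m3": m.slope, "slope_se_g_m3": m.slope_se,
            "resid_se_g_m2": m.resid_se, "adj_r2": m.adj_r2,
            "t_stat": m.t_stat, "p_value": m.p_value,
            "loocv_pct": m.loocv_pct, "skipped": False,
        })
    table = pd.DataFrame(rows)
    fitted = table[~table["skipped"]]
    if len(fitted):
        fitted = fitted.sort_values("slope_g_m3")
    skipped = table[table["skipped"]]
    return pd.concat([fitted, skipped], ignore_index=True)
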