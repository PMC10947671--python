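"""Census-tract aggregation and socioeconomic disparity analysis.

Cell-level diversity maps are aggregated to tracts by area-weighted means of
the intersecting grid cells. Disparities are quantified three ways:

* Welch two-sample t-tests comparing disadvantaged (DAC) and other tracts;
* Pearson correlations between diversity metrics and sociodemographic
  variables;
* linear mixed models (the "GLMM with normal distribution" formulation):
  ``outcome = b0 + b1*SES + b2*pop_density + county intercept + e`` where the
  residuals carry an exponential spatial correlation on tract centroids and
  the county intercept is a random effect. The model is fitted by REML with
  the variance-ratio and range parameters profiled out numerically; Wald 95%
  confidence intervals are reported for the SES slope. Sensitivity analyses
  fit a full multi-SES model with backward elimination (ML-based AIC/BIC) and
  NDVI-adjusted single-SES models.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import cdist
from shapely.geometry import box
from shapely.strtree import STRtree

from biodivmap.errors import FitError, GeometryError, InsufficientDataError
from biodivmap.ingest import GridSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def tract_geometries(tracts: pd.DataFrame):
    """Shapely polygons from a ``geometry`` column or rectangle bounds columns."""
    if "geometry" in tracts.columns:
        geoms = list(tracts["geometry"])
    else:
        needed = {"xmin", "ymin", "xmax", "ymax"}
        if not needed <= set(tracts.columns):
            raise GeometryError("tracts need a geometry column or xmin/ymin/xmax/ymax bounds")
        geoms = [box(r.xmin, r.ymin, r.xmax, r.ymax) for r in tracts.itertuples()]
    for tid, g in zip(tracts["tract_id"], geoms):
        if g is None or g.is_empty or not g.is_valid:
            raise GeometryError(f"invalid geometry for tract {tid}")
    return geoms


def summarize_to_tracts(
    cell_values: pd.DataFrame,
    grid: GridSpec,
    tracts: pd.DataFrame,
    value_cols: list[str],
) -> pd.DataFrame:
    """Area-weighted tract means of per-cell values.

    ``cell_values`` maps cell_id to one or more value columns covering the
    grid. Tract values are means of intersecting cells weighted by
    intersection area; tracts without any intersection get NaN and a
    ``missing`` flag.
    """
    geoms = tract_geometries(tracts)
    cell_boxes = [box(*grid.cell_bounds(cid)) for cid in range(grid.n_cells)]
    tree = STRtree(cell_boxes)
    vals = cell_values.set_index("cell_id")[value_cols]

    out_rows = []
    for (_, trow), geom in zip(tracts.iterrows(), geoms):
        idx = tree.query(geom)
        weights, ids = [], []
        for ci in idx:
            inter = cell_boxes[ci].intersection(geom)
            if inter.area > 0 and ci in vals.index:
                weights.append(inter.area)
                ids.append(ci)
        row = {"tract_id": trow["tract_id"], "missing": len(ids) == 0}
        for col in value_cols:
            if ids:
                v = vals.loc[ids, col].to_numpy(float)
                w = np.asarray(weights)
                ok = np.isfinite(v)
                row[f"mean_{col}"] = float(np.average(v[ok], weights=w[ok])) if ok.any() else np.nan
            else:
                row[f"mean_{col}"] = np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# simple comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    tracts: pd.DataFrame, metrics: list[str], flag_col: str = "dac"
) -> pd.DataFrame:
    """Welch t-test per metric between flagged and unflagged tracts."""
    g1 = tracts[tracts[flag_col].astype(bool)]
    g0 = tracts[~tracts[flag_col].astype(bool)]
    if len(g1) < 2 or len(g0) < 2:
        raise InsufficientDataError("both groups need >= 2 tracts for a t-test")
    rows = []
    for m in metrics:
        a = g1[m].dropna().to_numpy(float)
        b = g0[m].dropna().to_numpy(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise InsufficientDataError(f"zero variance in both groups for {m}")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "metric": m,
                "flagged_mean": float(a.mean()),
                "flagged_sd": float(a.std(ddof=1)),
                "other_mean": float(b.mean()),
                "other_sd": float(b.std(ddof=1)),
                "t": float(t),
                "p_value": float(p),
                "n_flagged": len(a),
                "n_other": len(b),
            }
        )
    return pd.DataFrame(rows)


def correlate(tracts: pd.DataFrame, outcomes: list[str], variables: list[str]) -> pd.DataFrame:
    """Pearson r between each outcome and each variable, with pair counts."""
    rows = []
    for o in outcomes:
        for v in variables:
            sub = tracts[[o, v]].dropna()
            if len(sub) < 3 or sub[o].std() == 0 or sub[v].std() == 0:
                rows.append({"outcome": o, "variable": v, "r": np.nan, "n": len(sub)})
                continue
            r, _ = stats.pearsonr(sub[o], sub[v])
            rows.append({"outcome": o, "variable": v, "r": float(r), "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial linear mixed model
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """REML fit of the spatially correlated county-intercept model."""

    ses_var: str
    outcome: str
    beta: float  # SES fixed effect, outcome units per % SES
    se: float
    ci_low: float
    ci_high: float
    coefficients: dict[str, float]
    coefficient_ses: dict[str, float]
    spatial_range: float  # exponential correlation range (0 = independent)
    county_var: float
    resid_var: float
    n: int
    reml_criterion: float
    converged: bool
    fallback_independent: bool = False
    aic: float = float("nan")  # ML-based, filled when requested
    bic: float = float("nan")


def _reml_profile(
    y: np.ndarray,
    X: np.ndarray,
    dist: np.ndarray,
    Z: np.ndarray | None,
    log_g: float,
    log_range: float,
    use_spatial: bool,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled REML criterion; returns (criterion, beta, cov_beta_unit, sigma2)."""
    n, p = X.shape
    if use_spatial:
        with np.errstate(over="ignore", under="ignore"):
            # a collapsing range turns the correlation into an identity: fine
            v0 = np.exp(-np.clip(dist / max(math.exp(log_range), 1e-300), 0.0, 700.0))
    else:
        v0 = np.eye(n)
    if Z is not None:
        v0 = v0 + math.exp(log_g) * (Z @ Z.T)
    try:
        c = np.linalg.cholesky(v0 + 1e-10 * np.eye(n))
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(p), np.eye(p), np.nan
    logdet_v = 2.0 * float(np.log(np.diag(c)).sum())
    xi = np.linalg.solve(c, X)
    yi = np.linalg.solve(c, y)
    xtvx = xi.T @ xi
    try:
        cov_unit = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(p), np.eye(p), np.nan
    beta = cov_unit @ (xi.T @ yi)
    r = yi - xi @ beta
    rss = float(r @ r)
    sigma2 = rss / (n - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0 or sigma2 <= 0:
        return np.inf, beta, cov_unit, sigma2
    crit = (n - p) * math.log(sigma2) + logdet_v + logdet_xtvx
    return crit, beta, cov_unit, sigma2


def fit_spatial_lmm(
    tracts: pd.DataFrame,
    ses_var: str,
    outcome: str,
    adjust: tuple[str, ...] = ("pop_density",),
    county_col: str = "county",
    coord_cols: tuple[str, str] = ("x", "y"),
    spatial: bool = True,
    county: bool = True,
    compute_ic: bool = False,
) -> MixedModelFit:
    """Linear mixed model for one SES variable with spatial residuals.

    With ``spatial=False`` and ``county=False`` the fit degenerates exactly to
    ordinary least squares (a useful independence limit). Non-convergence of
    the variance optimization falls back to the independent-residual model
    with ``fallback_independent=True``.
    """
    cols = [outcome, ses_var, *adjust, county_col, *coord_cols]
    data = tracts.dropna(subset=[c for c in cols if c in tracts.columns]).reset_index(drop=True)
    n = len(data)
    if n < 30:
        raise InsufficientDataError(f"spatial LMM needs >= 30 tracts, got {n}")
    counties = data[county_col].astype(str)
    if county and counties.nunique() < 3:
        raise InsufficientDataError("spatial LMM needs >= 3 counties")

    y = data[outcome].to_numpy(float)
    names = ["intercept", ses_var, *adjust]
    X = np.column_stack([np.ones(n)] + [data[c].to_numpy(float) for c in (ses_var, *adjust)])
    coords = data[list(coord_cols)].to_numpy(float)
    dist = cdist(coords, coords)
    Z = None
    if county:
        dummies = pd.get_dummies(counties)
        Z = dummies.to_numpy(float)

    scale0 = max(np.median(dist[dist > 0]) if (dist > 0).any() else 1.0, 1e-9)
    converged = True
    fallback = False
    if spatial or county:
        def objective(theta: np.ndarray) -> float:
            log_g = theta[0] if county else -np.inf
            log_r = theta[1] if spatial else 0.0
            crit, *_ = _reml_profile(y, X, dist, Z, log_g, log_r, spatial)
            return crit

        x0s = []
        base = [math.log(0.5) if county else 0.0, math.log(scale0) if spatial else 0.0]
        x0s.append(np.array(base))
        x0s.append(np.array([base[0] - 2.0, base[1] + (1.0 if spatial else 0.0)]))
        best = None
        for x0 in x0s:
            res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            converged = False
            fallback = True
            theta = np.array([-np.inf, 0.0])
        else:
            converged = bool(best.success)
            theta = best.x
        log_g = theta[0] if (county and not fallback) else -np.inf
        log_r = theta[1] if (spatial and not fallback) else 0.0
        use_spatial = spatial and not fallback
    else:
        log_g, log_r, use_spatial = -np.inf, 0.0, False

    crit, beta, cov_unit, sigma2 = _reml_profile(
        y, X, dist, Z if (county and not fallback) else None, log_g, log_r, use_spatial
    )
    se = np.sqrt(np.maximum(np.diag(cov_unit) * sigma2, 0.0))
    j = names.index(ses_var)
    z975 = stats.norm.ppf(0.975)
    g = math.exp(log_g) if np.isfinite(log_g) else 0.0
    fit = MixedModelFit(
        ses_var=ses_var,
        outcome=outcome,
        beta=float(beta[j]),
        se=float(se[j]),
        ci_low=float(beta[j] - z975 * se[j]),
        ci_high=float(beta[j] + z975 * se[j]),
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
        coefficient_ses={nm: float(s) for nm, s in zip(names, se)},
        spatial_range=float(math.exp(log_r)) if use_spatial else 0.0,
        county_var=float(g * sigma2),
        resid_var=float(sigma2),
        n=n,
        reml_criterion=float(crit),
        converged=converged,
        fallback_independent=fallback,
    )
    if compute_ic:
        fit.aic, fit.bic = _ml_information_criteria(
            y, X, dist, Z if county else None, log_g, log_r, use_spatial, county, spatial
        )
    return fit


def _ml_information_criteria(
    y, X, dist, Z, log_g, log_r, use_spatial, county, spatial
) -> tuple[float, float]:
    """ML log-likelihood at the REML variance parameters -> AIC/BIC."""
    n, p = X.shape
    if use_spatial:
        with np.errstate(over="ignore", under="ignore"):
            v0 = np.exp(-np.clip(dist / max(math.exp(log_r), 1e-300), 0.0, 700.0))
    else:
        v0 = np.eye(n)
    if Z is not None and np.isfinite(log_g):
        v0 = v0 + math.exp(log_g) * (Z @ Z.T)
    c = np.linalg.cholesky(v0 + 1e-10 * np.eye(n))
    xi = np.linalg.solve(c, X)
    yi = np.linalg.solve(c, y)
    beta = np.linalg.lstsq(xi, yi, rcond=None)[0]
    r = yi - xi @ beta
    sigma2 = float(r @ r) / n
    logdet_v = 2.0 * float(np.log(np.diag(c)).sum())
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_v + n)
    k = p + 1 + (1 if county else 0) + (1 if spatial else 0)
    return float(-2 * ll + 2 * k), float(-2 * ll + k * math.log(n))


def sensitivity_models(
    tracts: pd.DataFrame,
    ses_set: tuple[str, ...] = ("education_pct", "linguistic_isolation_pct", "unemployment_pct"),
    outcome: str = "mean_D0",
    ndvi_col: str = "ndvi",
    **lmm_kwargs,
) -> dict:
    """Full multi-SES model, backward elimination, and NDVI-adjusted fits.

    The full model includes every SES variable in ``ses_set`` (poverty and
    housing burden are excluded upstream to avoid collinearity) plus the
    population-density adjustment. Backward elimination removes, at each step,
    the variable whose removal lowers the ML AIC most (BIC is reported
    alongside); NDVI-adjusted single-SES models quantify confounding by
    greenness.
    """
    full = _fit_multi(tracts, list(ses_set), outcome, compute_ic=True, **lmm_kwargs)
    steps = [{"variables": list(ses_set), "aic": full["aic"], "bic": full["bic"]}]
    current = list(ses_set)
    while len(current) > 1:
        trials = []
        for v in current:
            rest = [u for u in current if u != v]
            fit = _fit_multi(tracts, rest, outcome, compute_ic=True, **lmm_kwargs)
            trials.append((fit["aic"], fit["bic"], v, rest))
        trials.sort()
        best_aic, best_bic, dropped, rest = trials[0]
        if best_aic >= steps[-1]["aic"] - 1e-9:
            break
        steps.append({"variables": rest, "aic": best_aic, "bic": best_bic, "dropped": dropped})
        current = rest

    ndvi_fits = []
    if ndvi_col in tracts.columns:
        for v in ses_set:
            ndvi_fits.append(
                fit_spatial_lmm(
                    tracts, v, outcome, adjust=("pop_density", ndvi_col), **lmm_kwargs
                )
            )
    return {"full_model": full, "backward_steps": steps, "ndvi_adjusted": ndvi_fits}


def _fit_multi(
    tracts: pd.DataFrame, ses_vars: list[str], outcome: str, compute_ic: bool, **lmm_kwargs
) -> dict:
    """Multi-SES fit expressed through the single-SES engine via `adjust`."""
    first, rest = ses_vars[0], tuple(ses_vars[1:])
    fit = fit_spatial_lmm(
        tracts, first, outcome, adjust=rest + ("pop_density",), compute_ic=compute_ic, **lmm_kwargs
    )
    return {
        "variables": list(ses_vars),
        "coefficients": fit.coefficients,
        "fit": fit,
        "aic": fit.aic,
        "bic": fit.bic,
    }
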