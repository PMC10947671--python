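"""Quasi-Poisson trend models (GLM and GAM) over screened covariates.

The GLM path fits a log-link quasi-Poisson regression on the standardized
predictors (plus the longitude coordinate) and performs both-direction
stepwise selection on a quasi-AIC (deviance scaled by the full model's
Pearson dispersion plus 2 per parameter). The GAM path delegates to the
in-package penalized additive model: univariate smooths per predictor plus a
2-D thin-plate spatial smooth on the cell centroids, with REML/double-penalty
smoothing selection so irrelevant terms shrink away.

Both paths expose the same ``TrendModel`` surface: per-cell fitted mean,
prediction with standard errors on the response scale, the dispersion
estimate and the fraction of deviance explained.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from biodivmap.errors import FitError
from biodivmap.spatial.gam import GamFit, fit_gam

logger = logging.getLogger(__name__)

TrendFamily = Literal["GLM", "GAM"]


@dataclass
class TrendModel:
    """Fitted trend with a uniform predict surface."""

    family: TrendFamily
    selected_terms: list[str]
    dispersion: float
    deviance_explained: float
    fitted: np.ndarray  # training-cell means
    lon_stats: tuple[float, float] | None = None  # (mean, sd) behind "__lon__"
    constant_value: float | None = None  # degenerate zero-variance response
    _glm_result: object | None = None
    _gam_result: GamFit | None = None

    def predict(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(mu, se_mu) at the cells of ``table`` (needs predictor and x/y columns)."""
        if self.constant_value is not None:
            n = len(table)
            return np.full(n, self.constant_value), np.zeros(n)
        if self.family == "GLM":
            if self.lon_stats is not None:
                table = table.copy()
                table["__lon__"] = (table["x"] - self.lon_stats[0]) / (self.lon_stats[1] or 1.0)
            xm = _glm_design(table, self.selected_terms)
            pred = self._glm_result.get_prediction(xm)
            mu = np.asarray(pred.predicted_mean, float)
            se = np.asarray(pred.se_mean, float)
            return mu, se
        gam = self._gam_result
        X = {name: table[name].to_numpy(float) for name in gam.term_names if name != "__space__"}
        coords = table[["x", "y"]].to_numpy(float) if gam.has_spatial else None
        return gam.predict(X, coords)


def _glm_design(table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    cols += [table[t].to_numpy(float) for t in terms]
    return np.column_stack(cols)


def _fit_quasi_poisson(xm: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer counts are fine for quasi-likelihood
        model = sm.GLM(y, xm, family=sm.families.Poisson())
        return model.fit(scale="X2")


def _stepwise_qaic(
    table: pd.DataFrame, y: np.ndarray, candidates: list[str], max_terms: int
) -> list[str]:
    """Both-direction stepwise minimizing QAIC = deviance/phi_full + 2(p+1)."""
    full = _fit_quasi_poisson(_glm_design(table, candidates), y)
    phi = max(float(full.scale), 1e-8)

    def qaic(terms: list[str]) -> float:
        res = _fit_quasi_poisson(_glm_design(table, terms), y)
        return float(res.deviance) / phi + 2.0 * (len(terms) + 1)

    current = list(candidates[:max_terms])
    best = qaic(current)
    improved = True
    while improved:
        improved = False
        for t in list(current):  # backward
            trial = [u for u in current if u != t]
            score = qaic(trial)
            if score < best - 1e-9:
                current, best, improved = trial, score, True
        for t in candidates:  # forward
            if t in current or len(current) >= max_terms:
                continue
            trial = current + [t]
            score = qaic(trial)
            if score < best - 1e-9:
                current, best, improved = trial, score, True
    return current


def fit_trend(
    table: pd.DataFrame,
    y: np.ndarray,
    predictors: list[str],
    family: TrendFamily = "GAM",
    include_longitude: bool = True,
    min_cells_per_term: int = 10,
    k_univariate: int = 8,
    n_space_knots: int = 49,
) -> TrendModel:
    """Fit the quasi-Poisson trend on training cells.

    ``table`` holds standardized predictors plus centroid coordinates x/y.
    The GLM path adds longitude (x) to the candidate set (latitude is left to
    the GAM's spatial smooth). A guard limits the number of terms to one per
    ``min_cells_per_term`` training cells, keeping fits identifiable on small
    training folds.
    """
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise FitError("trend response must be strictly positive under the log link")
    if len(table) != y.shape[0]:
        raise ValueError("table and y disagree in length")
    if np.ptp(y) == 0.0:
        # a constant response carries no trend information; short-circuit to
        # the exact intercept-only model (IRLS engines reject this corner)
        return TrendModel(
            family=family,
            selected_terms=[],
            dispersion=0.0,
            deviance_explained=0.0,
            fitted=y.copy(),
            constant_value=float(y[0]),
        )
    max_terms = max(len(table) // min_cells_per_term, 1)
    if len(predictors) > max_terms:
        logger.info("trend: trimming %d predictors to %d (guard)", len(predictors), max_terms)
        predictors = predictors[:max_terms]

    if family == "GLM":
        candidates = list(predictors)
        if include_longitude and "x" in table.columns:
            xsd = table["x"].std()
            if xsd > 0:
                table = table.copy()
                table["__lon__"] = (table["x"] - table["x"].mean()) / xsd
                candidates.append("__lon__")
        selected = _stepwise_qaic(table, y, candidates, max_terms)
        if not selected:
            selected = []
        res = _fit_quasi_poisson(_glm_design(table, selected), y)
        if not np.all(np.isfinite(res.params)):
            raise FitError("GLM failed to converge (non-finite coefficients)")
        null_dev = float(
            _fit_quasi_poisson(np.ones((len(table), 1)), y).deviance
        )
        dev_expl = float(np.clip(1.0 - res.deviance / max(null_dev, 1e-12), 0.0, 1.0))
        return TrendModel(
            family="GLM",
            selected_terms=selected,
            dispersion=float(res.scale),
            deviance_explained=dev_expl,
            fitted=np.asarray(res.fittedvalues, float),
            lon_stats=(
                (float(table["x"].mean()), float(table["x"].std()))
                if "__lon__" in selected
                else None
            ),
            _glm_result=res,
        )

    X = {p: table[p].to_numpy(float) for p in predictors}
    coords = table[["x", "y"]].to_numpy(float)
    n_space_knots = min(n_space_knots, max(8, len(table) // 3))
    gam = fit_gam(
        X, y, coords=coords, k_univariate=k_univariate, n_space_knots=n_space_knots
    )
    return TrendModel(
        family="GAM",
        selected_terms=list(predictors) + ["s(x,y)"],
        dispersion=gam.phi,
        deviance_explained=gam.deviance_explained,
        fitted=gam.fitted,
        _gam_result=gam,
    )
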