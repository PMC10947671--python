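"""Ordinary kriging and regression kriging.

Ordinary kriging (OK) solves, for each prediction point, the standard system
in semivariance form with the unbiasedness constraint (weights sum to one)
over a global neighborhood (all observations):

    [ Gamma  1 ] [ lambda ]   [ gamma_0 ]
    [ 1'     0 ] [ mu     ] = [ 1       ]

with prediction ``sum lambda_i z_i`` and kriging variance
``sum lambda_i gamma(s_i, s0) + mu``. Coincident points get semivariance 0
(the nugget is a discontinuity at the origin), so the predictor is exact at
observed locations and has zero variance there when the nugget is zero.

Regression kriging composes a fitted trend with OK of its response-scale
residuals: ``yhat = mu_trend + r_ok``; pure-regression variants use a zero
residual field. Final predictions are floored at the minimum observed value
so that residual superposition cannot produce implausibly small diversity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist

from biodivmap.errors import GeometryError, KrigingError, NumericalContractError
from biodivmap.spatial.variogram import VariogramModel


@dataclass(frozen=True)
class KrigingPrediction:
    """Per-location trend + kriged-residual prediction with uncertainty."""

    cell_id: int
    trend: float
    residual: float
    prediction: float
    ok_variance: float
    se: float


def _gamma_matrix(d: np.ndarray, vg: VariogramModel) -> np.ndarray:
    g = vg(d)
    return np.where(d == 0.0, 0.0, g)


def ordinary_krige(
    obs_coords: np.ndarray,
    obs_values: np.ndarray,
    pred_coords: np.ndarray,
    vg: VariogramModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Global-neighborhood OK; returns (predictions, kriging variances).

    Raises ``KrigingError`` if the augmented system stays singular after one
    jitter retry (1e-10 added to the semivariance diagonal).
    """
    obs_coords = np.asarray(obs_coords, float)
    obs_values = np.asarray(obs_values, float)
    pred_coords = np.asarray(pred_coords, float)
    n = obs_coords.shape[0]
    if n < 2:
        raise GeometryError("ordinary kriging needs at least 2 observations")
    d_obs = cdist(obs_coords, obs_coords)
    if d_obs.max() <= 0:
        raise GeometryError("all observations are coincident")

    gamma = _gamma_matrix(d_obs, vg)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0

    b = np.empty((n + 1, pred_coords.shape[0]))
    b[:n] = _gamma_matrix(cdist(obs_coords, pred_coords), vg)
    b[n] = 1.0

    for attempt in range(2):
        try:
            lu, piv = lu_factor(a)
            w = lu_solve((lu, piv), b)
            if not np.all(np.isfinite(w)):
                raise np.linalg.LinAlgError("non-finite kriging weights")
            break
        except (np.linalg.LinAlgError, ValueError):
            if attempt == 1:
                raise KrigingError("kriging system singular after jitter retry")
            a[:n, :n][np.diag_indices(n)] += 1e-10

    preds = w[:n].T @ obs_values
    variances = np.maximum((w * b).sum(axis=0), 0.0)
    return preds, variances


def ok_weights(
    obs_coords: np.ndarray, pred_point: np.ndarray, vg: VariogramModel
) -> tuple[np.ndarray, float]:
    """Weights and Lagrange multiplier for a single prediction point."""
    obs_coords = np.asarray(obs_coords, float)
    n = obs_coords.shape[0]
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = _gamma_matrix(cdist(obs_coords, obs_coords), vg)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = _gamma_matrix(cdist(obs_coords, np.asarray(pred_point, float)[None, :]), vg).ravel()
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    return sol[:n], float(sol[n])


def regression_krige(
    trend_pred: np.ndarray,
    obs_coords: np.ndarray,
    obs_values: np.ndarray,
    obs_trend: np.ndarray,
    pred_coords: np.ndarray,
    vg_resid: VariogramModel | None,
    cell_ids: np.ndarray | None = None,
    trend_se: np.ndarray | None = None,
    floor: float | None = None,
) -> list[KrigingPrediction]:
    """Trend + kriged residual at every prediction location.

    ``vg_resid=None`` selects the pure-regression variant (zero residual
    field, zero OK variance). ``floor`` defaults to the minimum observed
    value; pass ``-inf`` to disable flooring.
    """
    trend_pred = np.asarray(trend_pred, float)
    pred_coords = np.asarray(pred_coords, float)
    obs_values = np.asarray(obs_values, float)
    m = pred_coords.shape[0]
    if trend_pred.shape[0] != m:
        raise ValueError("trend_pred and pred_coords disagree in length")
    if vg_resid is None:
        resid = np.zeros(m)
        ok_var = np.zeros(m)
    else:
        residuals = obs_values - np.asarray(obs_trend, float)
        resid, ok_var = ordinary_krige(obs_coords, residuals, pred_coords, vg_resid)
    pred = trend_pred + resid
    if floor is None:
        floor = float(obs_values.min())
    pred = np.maximum(pred, floor)
    tse = np.zeros(m) if trend_se is None else np.asarray(trend_se, float)
    se = prediction_standard_error(tse, ok_var)
    ids = np.arange(m) if cell_ids is None else np.asarray(cell_ids)
    return [
        KrigingPrediction(
            cell_id=int(ids[i]),
            trend=float(trend_pred[i]),
            residual=float(resid[i]),
            prediction=float(pred[i]),
            ok_variance=float(ok_var[i]),
            se=float(se[i]),
        )
        for i in range(m)
    ]


def prediction_standard_error(
    trend_se: np.ndarray | float, ok_variance: np.ndarray | float
) -> np.ndarray:
    """Combined SE = sqrt(trend_se^2 + ok_variance), assuming independence."""
    trend_se = np.asarray(trend_se, float)
    ok_variance = np.asarray(ok_variance, float)
    if np.any(trend_se < 0):
        raise NumericalContractError("negative trend standard error")
    if np.any(ok_variance < 0):
        raise NumericalContractError("negative kriging variance")
    return np.sqrt(trend_se**2 + ok_variance)
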