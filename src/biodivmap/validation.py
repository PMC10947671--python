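"""Cross-validated comparison of the five extrapolation models and final maps.

The five methods are OK (ordinary kriging of the observed metric alone), GLM
and GAM (pure quasi-Poisson regression trends) and GLM OK / GAM OK
(regression kriging: trend plus ordinary kriging of its response-scale
residuals). Performance is assessed by k-fold cross-validation over the
saturated cells: within each fold the covariates are re-standardized and
re-screened, the trend refitted, and the optimum residual variogram refitted
on the training cells only. Held-out predictions are pooled over folds and
summarized by Pearson correlation, MAE, RMAE (% of mean observed), RMSE and
RRMSE (% of mean observed).

The final ("optimized") map retains extrapolated values in unsaturated cells
and replaces the values in saturated cells with the observed coverage-
standardized estimates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from biodivmap.errors import (
    CompositionError,
    GeometryError,
    InsufficientDataError,
    VariogramError,
)
from biodivmap.spatial.covariates import CovariateStack, screen_covariates
from biodivmap.spatial.kriging import ordinary_krige, prediction_standard_error
from biodivmap.spatial.trend import fit_trend
from biodivmap.spatial.variogram import empirical_variogram, fit_variogram, pure_nugget

logger = logging.getLogger(__name__)

METHODS: tuple[str, ...] = ("OK", "GLM", "GAM", "GLM_OK", "GAM_OK")


def prediction_metrics(observed: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """corr / MAE / RMAE% / RMSE / RRMSE% of predictions against observations."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need >= 2 aligned observation/prediction pairs")
    err = predicted - observed
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    mean_obs = float(observed.mean())
    corr = float(np.corrcoef(observed, predicted)[0, 1]) if observed.std() > 0 and predicted.std() > 0 else np.nan
    return {
        "corr": corr,
        "MAE": mae,
        "RMAE": 100.0 * mae / mean_obs,
        "RMSE": rmse,
        "RRMSE": 100.0 * rmse / mean_obs,
    }


def _fit_residual_variogram(coords: np.ndarray, resid: np.ndarray, n_bins: int = 15):
    try:
        bins = empirical_variogram(coords, resid, n_bins=n_bins)
        return fit_variogram(bins)
    except (VariogramError, GeometryError) as exc:
        logger.warning("residual variogram fit failed (%s); using pure nugget", exc)
        return pure_nugget(float(np.var(resid)))


def fit_and_predict(
    method: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    y_col: str,
    predictors: list[str],
    collinearity_r: float = 0.8,
    outcome_r: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one method on ``train`` and predict ``test``.

    Returns (predictions, standard errors, training fitted values). Both
    frames need cell_id, x, y and the predictor columns; ``train`` needs the
    observed metric ``y_col``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = train[y_col].to_numpy(float)
    tr_coords = train[["x", "y"]].to_numpy(float)
    te_coords = test[["x", "y"]].to_numpy(float)

    if method == "OK":
        vg = _fit_residual_variogram(tr_coords, y)
        pred, var = ordinary_krige(tr_coords, y, te_coords, vg)
        fitted, _ = ordinary_krige(tr_coords, y, tr_coords, vg)
        pred = np.maximum(pred, float(y.min()))
        return pred, np.sqrt(var), fitted

    both = pd.concat([train, test], ignore_index=True)
    train_mask = np.zeros(len(both), dtype=bool)
    train_mask[: len(train)] = True
    stack = CovariateStack(
        table=both[["cell_id", "x", "y", *predictors]], predictors=list(predictors)
    ).standardize(train_mask=train_mask)
    selected = screen_covariates(
        stack,
        y,
        train_mask=train_mask,
        collinearity_r=collinearity_r,
        outcome_r=outcome_r,
    )
    tab = stack.table
    tr_tab = tab.iloc[: len(train)].reset_index(drop=True)
    te_tab = tab.iloc[len(train):].reset_index(drop=True)
    family = "GAM" if method.startswith("GAM") else "GLM"
    trend = fit_trend(tr_tab, y, selected, family=family)
    mu_te, se_te = trend.predict(te_tab)
    mu_tr, _ = trend.predict(tr_tab)

    if method.endswith("_OK"):
        resid = y - mu_tr
        vg = _fit_residual_variogram(tr_coords, resid)
        r_te, var_te = ordinary_krige(tr_coords, resid, te_coords, vg)
        r_tr, _ = ordinary_krige(tr_coords, resid, tr_coords, vg)
        pred = mu_te + r_te
        fitted = mu_tr + r_tr
        se = prediction_standard_error(se_te, var_te)
    else:
        pred, fitted, se = mu_te, mu_tr, se_te
    pred = np.maximum(pred, float(y.min()))
    return pred, se, fitted


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Fold label per index; sizes differ by at most one; seeded permutation."""
    if n < k:
        raise InsufficientDataError(f"cannot make {k} folds from {n} cells")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


def cross_validate(
    cells: pd.DataFrame,
    y_col: str,
    predictors: list[str],
    methods: tuple[str, ...] = METHODS,
    k: int = 10,
    seed: int = 0,
    min_cells: int | None = None,
) -> pd.DataFrame:
    """k-fold CV of the requested methods on the saturated cells.

    Returns a long frame with columns method, split (training/validation),
    corr, MAE, RMAE, RMSE, RRMSE, n. Validation metrics are pooled over the
    held-out predictions; training metrics (reported for the regression
    methods, as fitted-vs-observed within folds) are averaged across folds.
    """
    n = len(cells)
    floor = 5 * k if min_cells is None else min_cells
    if n < floor:
        raise InsufficientDataError(f"CV needs >= {floor} saturated cells, got {n}")
    folds = make_folds(n, k, seed)
    cells = cells.reset_index(drop=True)

    pooled: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    pooled_obs: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    train_metrics: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    for f in range(k):
        train = cells[folds != f].reset_index(drop=True)
        test = cells[folds == f].reset_index(drop=True)
        for m in methods:
            pred, _, fitted = fit_and_predict(m, train, test, y_col, predictors)
            pooled[m].append(pred)
            pooled_obs[m].append(test[y_col].to_numpy(float))
            train_metrics[m].append(prediction_metrics(train[y_col].to_numpy(float), fitted))

    rows = []
    for m in methods:
        obs = np.concatenate(pooled_obs[m])
        pred = np.concatenate(pooled[m])
        val = prediction_metrics(obs, pred)
        rows.append({"method": m, "split": "validation", "n": len(obs), **val})
        if m in ("GLM", "GAM"):
            avg = {
                key: float(np.mean([tm[key] for tm in train_metrics[m]]))
                for key in ("corr", "MAE", "RMAE", "RMSE", "RRMSE")
            }
            rows.append({"method": m, "split": "training", "n": n, **avg})
    return pd.DataFrame(rows)


def select_model(report: pd.DataFrame, metrics: list[str] | None = None) -> dict[str, str]:
    """Pick the best method per diversity metric and a consensus method.

    Ranking: lowest validation RRMSE, ties broken by higher correlation, then
    lower RMAE. The consensus is the majority winner across metrics; on a tie
    the method with the lowest mean RRMSE wins. ``report`` may carry a
    ``metric`` column; without one a single unnamed metric is assumed.
    """
    if "metric" not in report.columns:
        report = report.assign(metric="metric")
    winners: dict[str, str] = {}
    for metric, sub in report.groupby("metric"):
        val = sub[sub["split"] == "validation"].copy()
        val = val.sort_values(
            by=["RRMSE", "corr", "RMAE"], ascending=[True, False, True], kind="stable"
        )
        winners[str(metric)] = str(val.iloc[0]["method"])
    counts = pd.Series(list(winners.values())).value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) == 1:
        consensus = top[0]
    else:
        val = report[report["split"] == "validation"]
        mean_rrmse = val[val["method"].isin(top)].groupby("method")["RRMSE"].mean()
        consensus = str(mean_rrmse.idxmin())
    winners["consensus"] = consensus
    return winners


@dataclass
class FinalMap:
    """Per-cell map combining model predictions and observed estimates."""

    table: pd.DataFrame  # cell_id, value, provenance, se

    def summary(self) -> dict[str, float]:
        v = self.table["value"]
        return {
            "mean": float(v.mean()),
            "median": float(v.median()),
            "min": float(v.min()),
            "max": float(v.max()),
            "sd": float(v.std()),
        }


def compose_final_map(
    predictions: pd.DataFrame,
    observed: pd.DataFrame,
    value_col: str = "prediction",
    observed_col: str = "D",
) -> FinalMap:
    """Override predictions with observed estimates where available.

    ``predictions`` must cover every cell (cell_id, prediction, se);
    ``observed`` holds the saturated cells (cell_id, observed value). A cell
    with neither value raises ``CompositionError``.
    """
    pred = predictions.set_index("cell_id")
    obs = observed.set_index("cell_id")
    all_ids = pred.index.union(obs.index)
    missing = all_ids.difference(pred.index).difference(obs.index)
    if len(missing):
        raise CompositionError(f"cells with neither prediction nor observation: {list(missing)[:10]}")
    rows = []
    for cid in all_ids:
        if cid in obs.index:
            rows.append(
                {
                    "cell_id": cid,
                    "value": float(obs.at[cid, observed_col]),
                    "provenance": "observed",
                    "se": 0.0,
                }
            )
        else:
            rows.append(
                {
                    "cell_id": cid,
                    "value": float(pred.at[cid, value_col]),
                    "provenance": "modeled",
                    "se": float(pred.at[cid, "se"]) if "se" in pred.columns else np.nan,
                }
            )
    return FinalMap(table=pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True))
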