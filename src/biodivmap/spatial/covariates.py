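"""Covariate stack handling: gap filling, standardization, screening.

The stack is a per-cell table of candidate predictors plus cell centroid
coordinates. Missing values are filled with the mean of non-missing neighbors
within a fixed radius (default 8 km) of the cell centroid. Before modeling,
predictors are standardized to mean 0 / sd 1 over the training cells, then
screened in two passes: collinear pairs (|r| > 0.8) lose the member less
correlated with the outcome, and predictors with |r| <= 0.1 against the
outcome are dropped. Latitude (the y coordinate) is excluded from the linear
(GLM) candidate set — it is collinear with longitude along the coastal
gradient — but both coordinates enter the GAM through the 2-D spatial smooth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from biodivmap.errors import ScreeningError

logger = logging.getLogger(__name__)


@dataclass
class CovariateStack:
    """Per-cell predictor table with coordinates and a standardization record."""

    table: pd.DataFrame  # cell_id, x, y, one column per predictor
    predictors: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"cell_id", "x", "y", *self.predictors}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    def standardize(self, train_mask: np.ndarray | None = None) -> "CovariateStack":
        """Standardize predictors to mean 0 / sd 1 on the training rows.

        ``train_mask`` is a boolean array aligned with the table rows; by
        default every row is a training row.
        """
        tab = self.table.copy()
        if train_mask is None:
            train = tab
        else:
            train = tab.loc[np.asarray(train_mask, bool)]
        means, sds = {}, {}
        for p in self.predictors:
            mu = float(train[p].mean())
            sd = float(train[p].std(ddof=0))
            means[p], sds[p] = mu, sd if sd > 0 else 1.0
            tab[p] = (tab[p] - means[p]) / sds[p]
        return CovariateStack(table=tab, predictors=list(self.predictors), means=means, sds=sds)


def fill_missing_covariate(stack: CovariateStack, radius_m: float = 8000.0) -> CovariateStack:
    """Fill missing predictor values with the mean of in-radius neighbors.

    A neighbor is any cell whose centroid lies within ``radius_m`` of the
    target centroid (the target itself is excluded since it has no value).
    Raises when some cell has no non-missing neighbor in radius, listing the
    offending (cell_id, predictor) pairs.
    """
    tab = stack.table.copy()
    coords = stack.coords
    offenders: list[tuple[int, str]] = []
    dist: np.ndarray | None = None
    for p in stack.predictors:
        vals = tab[p].to_numpy(float)
        miss = ~np.isfinite(vals)
        if not miss.any():
            continue
        if dist is None:
            dist = cdist(coords, coords)
        for i in np.flatnonzero(miss):
            near = (dist[i] <= radius_m) & ~miss & (np.arange(len(vals)) != i)
            if not near.any():
                offenders.append((int(tab["cell_id"].iloc[i]), p))
                continue
            vals[i] = vals[near].mean()
        tab[p] = vals
    if offenders:
        raise ScreeningError(f"no neighbor within {radius_m} m for: {offenders[:10]}")
    return CovariateStack(
        table=tab, predictors=list(stack.predictors), means=dict(stack.means), sds=dict(stack.sds)
    )


def screen_covariates(
    stack: CovariateStack,
    y: pd.Series | np.ndarray,
    train_mask: np.ndarray | None = None,
    collinearity_r: float = 0.8,
    outcome_r: float = 0.1,
) -> list[str]:
    """Two-pass predictor screening against the outcome on training rows.

    Pass 1 walks collinear pairs (|r| > ``collinearity_r``) in descending |r|
    and drops the member with the smaller |cor(predictor, y)| until no pair
    exceeds the threshold. Pass 2 drops predictors with
    |cor(predictor, y)| <= ``outcome_r``. Raises if nothing survives; the
    survivors come back ordered by decreasing outcome correlation.
    """
    tab = stack.table
    if train_mask is None:
        train_mask = np.ones(len(tab), dtype=bool)
    X = tab.loc[np.asarray(train_mask, bool), stack.predictors].to_numpy(float)
    yv = np.asarray(y, float)
    if yv.shape[0] != X.shape[0]:
        raise ValueError("y must align with the training cells")

    names = list(stack.predictors)
    sd = X.std(axis=0)
    keep_var = sd > 0
    names = [n for n, k in zip(names, keep_var) if k]
    X = X[:, keep_var]
    if not names:
        raise ScreeningError("all predictors are constant on the training cells")

    ry = np.array(
        [abs(np.corrcoef(X[:, j], yv)[0, 1]) if X[:, j].std() > 0 else 0.0 for j in range(X.shape[1])]
    )
    rxx = np.corrcoef(X, rowvar=False)
    active = set(range(len(names)))
    pairs = [
        (abs(rxx[i, j]), i, j)
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(rxx[i, j]) > collinearity_r
    ]
    for _, i, j in sorted(pairs, reverse=True):
        if i in active and j in active:
            drop = j if ry[j] <= ry[i] else i
            active.discard(drop)
            logger.info(
                "screen: dropped %s (collinear with %s, |r|=%.2f)",
                names[drop],
                names[i if drop == j else j],
                abs(rxx[i, j]),
            )
    selected = [k for k in active if ry[k] > outcome_r]
    dropped_weak = [names[k] for k in sorted(active) if ry[k] <= outcome_r]
    if dropped_weak:
        logger.info("screen: dropped weak predictors %s (|r| <= %.2f)", dropped_weak, outcome_r)
    if not selected:
        raise ScreeningError("screening removed every predictor")
    # strongest outcome correlation first, so downstream term-count guards
    # keep the most informative predictors
    selected.sort(key=lambda k: (-ry[k], k))
    return [names[k] for k in selected]
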