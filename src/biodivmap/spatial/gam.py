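"""Penalized quasi-Poisson additive model with double-penalty shrinkage.

A log-link additive model for overdispersed counts (Var = phi * mu):

    log mu = beta_0 + sum_j f_j(x_j) + g(lon, lat)

* univariate smooths ``f_j`` are cubic P-splines (B-spline basis with a
  second-order difference penalty), sum-to-zero constrained;
* the spatial smooth ``g`` is a low-rank thin-plate radial basis
  (r^2 log r kernel on a deterministic knot subset) with its bending-energy
  penalty, the standard construction behind Duchon-type 2-D smooths;
* every term carries a second "null-space" penalty (the double-penalty
  device), so smoothing-parameter selection can shrink a whole term to zero
  effective degrees of freedom and irrelevant covariates drop out;
* smoothing parameters maximize the Laplace-approximate REML criterion via
  Fellner-Schall updates interleaved with penalized IRLS, and the dispersion
  is estimated from the Pearson statistic.

Fitting is deterministic given the data. The model is small-scale by design
(hundreds of cells, tens of basis functions per term).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, eigh, null_space
from scipy.spatial.distance import cdist

from biodivmap.errors import FitError

_LAM_MIN, _LAM_MAX = 1e-7, 1e9


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    return BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()


@dataclass
class _PSplineTerm:
    """Sum-to-zero constrained cubic P-spline for one covariate."""

    name: str
    knots: np.ndarray
    lo: float
    hi: float
    Z: np.ndarray  # constraint null-space transform (k x k-1)
    S_range: np.ndarray
    S_null: np.ndarray

    @classmethod
    def build(cls, name: str, x: np.ndarray, k: int = 8) -> "_PSplineTerm":
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        inner = np.linspace(lo, hi, k - 2)
        step = inner[1] - inner[0]
        knots = np.concatenate([inner[0] - step * np.arange(3, 0, -1), inner, inner[-1] + step * np.arange(1, 4)])
        B = _bspline_design(np.clip(x, lo, hi), knots)
        d2 = np.diff(np.eye(B.shape[1]), n=2, axis=0)
        S = d2.T @ d2
        Z = null_space(B.mean(axis=0, keepdims=True))
        Sz = Z.T @ S @ Z
        w, v = eigh(Sz)
        tol = max(w.max(), 1.0) * 1e-9
        null_vecs = v[:, w <= tol]
        return cls(
            name=name,
            knots=knots,
            lo=lo,
            hi=hi,
            Z=Z,
            S_range=Sz,
            S_null=null_vecs @ null_vecs.T,
        )

    def design(self, x: np.ndarray) -> np.ndarray:
        return _bspline_design(np.clip(x, self.lo, self.hi), self.knots) @ self.Z

    @property
    def width(self) -> int:
        return self.Z.shape[1]


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        k = r * r * np.log(r)
    return np.where(r > 0, k, 0.0)


@dataclass
class _ThinPlateTerm:
    """Low-rank thin-plate 2-D smooth on scaled coordinates.

    The radial block is constrained orthogonal to (1, x, y) at the knots; the
    unpenalized drift reduces to the two linear coordinate columns (the
    intercept lives in the model's own intercept), which the null-space
    penalty can shrink away.
    """

    knots: np.ndarray  # (K, 2) scaled
    center: np.ndarray
    scale: float
    Z: np.ndarray  # (K, K-3)
    S_range: np.ndarray  # penalty on radial coefficients
    S_null: np.ndarray  # identity on the 2 linear columns

    @classmethod
    def build(cls, coords: np.ndarray, n_knots: int = 49) -> "_ThinPlateTerm":
        center = coords.mean(axis=0)
        scale = float(np.abs(coords - center).max()) or 1.0
        sc = (coords - center) / scale
        uniq = np.unique(sc, axis=0)
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        uniq = uniq[order]
        k = min(n_knots, uniq.shape[0])
        idx = np.unique(np.linspace(0, uniq.shape[0] - 1, k).astype(int))
        knots = uniq[idx]
        if knots.shape[0] < 4:
            raise FitError("thin-plate smooth needs at least 4 distinct locations")
        E = _tps_kernel(cdist(knots, knots))
        T = np.column_stack([np.ones(knots.shape[0]), knots])
        Z = null_space(T.T)
        S = Z.T @ E @ Z
        S = (S + S.T) / 2.0
        w = eigh(S, eigvals_only=True)
        if w.min() < 0:  # conditional positive definiteness can wobble numerically
            S += (1e-10 - min(w.min(), 0.0)) * np.eye(S.shape[0])
        width = Z.shape[1] + 2
        s_null = np.zeros((width, width))
        s_null[-2:, -2:] = np.eye(2)
        s_range = np.zeros((width, width))
        s_range[: Z.shape[1], : Z.shape[1]] = S
        return cls(knots=knots, center=center, scale=scale, Z=Z, S_range=s_range, S_null=s_null)

    def design(self, coords: np.ndarray) -> np.ndarray:
        sc = (np.asarray(coords, float) - self.center) / self.scale
        radial = _tps_kernel(cdist(sc, self.knots)) @ self.Z
        return np.column_stack([radial, sc])

    @property
    def width(self) -> int:
        return self.Z.shape[1] + 2


@dataclass
class GamFit:
    """Fitted penalized quasi-Poisson additive model."""

    terms: list
    term_names: list[str]
    slices: list[slice]
    beta: np.ndarray
    V_beta: np.ndarray  # phi * (X'WX + S_lambda)^-1
    lambdas: np.ndarray
    phi: float
    edf_total: float
    edf_by_term: dict[str, float]
    deviance: float
    null_deviance: float
    fitted: np.ndarray
    has_spatial: bool

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return float(np.clip(1.0 - self.deviance / self.null_deviance, 0.0, 1.0))

    def _design(self, X: dict[str, np.ndarray], coords: np.ndarray | None) -> np.ndarray:
        n = next(iter(X.values())).shape[0] if X else coords.shape[0]
        cols = [np.ones((n, 1))]
        for name, term in zip(self.term_names, self.terms):
            if name == "__space__":
                if coords is None:
                    raise ValueError("model has a spatial smooth; coords required")
                cols.append(term.design(coords))
            else:
                cols.append(term.design(np.asarray(X[name], float)))
        return np.hstack(cols)

    def predict(
        self, X: dict[str, np.ndarray], coords: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mean response and its standard error at new cells."""
        xm = self._design(X, coords)
        eta = xm @ self.beta
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", xm, self.V_beta, xm), 0.0))
        return mu, mu * se_eta


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _pirls(
    xm: np.ndarray,
    y: np.ndarray,
    s_total: np.ndarray,
    eta0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    eta = eta0.copy()
    mu = np.exp(np.clip(eta, -30, 30))
    dev = _poisson_deviance(y, mu)
    beta = np.zeros(xm.shape[1])
    for _ in range(max_iter):
        w = mu
        z = eta + (y - mu) / mu
        xtw = xm.T * w
        h = xtw @ xm + s_total
        try:
            c = cho_factor(h)
        except np.linalg.LinAlgError:
            h = h + 1e-8 * np.eye(h.shape[0]) * max(np.trace(h) / h.shape[0], 1.0)
            c = cho_factor(h)
        beta = cho_solve(c, xtw @ z)
        eta = xm @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        new_dev = _poisson_deviance(y, mu)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    return beta, eta, mu, dev


def fit_gam(
    X: dict[str, np.ndarray],
    y: np.ndarray,
    coords: np.ndarray | None = None,
    k_univariate: int = 8,
    n_space_knots: int = 49,
    select: bool = True,
    max_outer: int = 40,
) -> GamFit:
    """Fit the additive model; ``select=True`` enables double-penalty shrinkage.

    ``X`` maps covariate names to training vectors; ``coords`` (n x 2) adds
    the 2-D spatial smooth. The outer loop alternates penalized IRLS with
    Fellner-Schall smoothing-parameter updates until the log-smoothing
    parameters stabilize.
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    if np.any(y <= 0):
        raise FitError("log-link quasi-Poisson trend requires strictly positive response")
    terms: list = []
    names: list[str] = []
    for name, x in X.items():
        terms.append(_PSplineTerm.build(name, np.asarray(x, float), k=k_univariate))
        names.append(name)
    if coords is not None:
        terms.append(_ThinPlateTerm.build(np.asarray(coords, float), n_knots=n_space_knots))
        names.append("__space__")
    if not terms:
        raise FitError("no terms to fit")

    cols = [np.ones((n, 1))]
    slices: list[slice] = []
    pos = 1
    for name, term in zip(names, terms):
        blk = term.design(np.asarray(X[name], float)) if name != "__space__" else term.design(coords)
        cols.append(blk)
        slices.append(slice(pos, pos + term.width))
        pos += term.width
    xm = np.hstack(cols)
    p = xm.shape[1]

    penalties: list[tuple[slice, np.ndarray]] = []
    for sl, term in zip(slices, terms):
        penalties.append((sl, term.S_range))
        if select:
            penalties.append((sl, term.S_null))

    def total_penalty(lam: np.ndarray) -> np.ndarray:
        s = np.zeros((p, p))
        for l, (sl, mat) in zip(lam, penalties):
            s[sl, sl] += l * mat
        return s

    lam = np.ones(len(penalties))
    eta = np.log(np.maximum(y, 0.5))
    beta = np.zeros(p)
    mu = np.exp(eta)
    for _ in range(max_outer):
        s_tot = total_penalty(lam)
        beta, eta, mu, dev = _pirls(xm, y, s_tot, eta)
        w = mu
        xtwx = (xm.T * w) @ xm
        h = xtwx + s_tot
        hinv = np.linalg.inv(h)
        edf = float(np.trace(hinv @ xtwx))
        pearson = float(np.sum((y - mu) ** 2 / mu))
        phi = max(pearson / max(n - edf, 1.0), 1e-8)

        # pseudo-inverse of the total penalty for the Fellner-Schall numerator;
        # the penalty is block-diagonal over terms, so invert per block with a
        # per-block tolerance (a global tolerance lets one heavily penalized
        # term swallow the small eigenvalues of the others)
        s_pinv = np.zeros_like(s_tot)
        for sl in slices:
            blk = (s_tot[sl, sl] + s_tot[sl, sl].T) / 2.0
            wvals, wvecs = eigh(blk)
            tol_e = max(wvals.max(), 1e-300) * 1e-12
            inv_vals = np.where(wvals > tol_e, 1.0 / np.maximum(wvals, tol_e), 0.0)
            s_pinv[sl, sl] = (wvecs * inv_vals) @ wvecs.T

        new_lam = lam.copy()
        for j, (sl, mat) in enumerate(penalties):
            num = float(np.sum(s_pinv[sl, sl] * mat) - np.sum(hinv[sl, sl] * mat))
            den = float(beta[sl] @ mat @ beta[sl])
            if den <= 1e-12 * max(np.abs(beta[sl]).max() ** 2, 1e-12) or den <= 0:
                new_lam[j] = _LAM_MAX
                continue
            ratio = phi * max(num, 1e-12) / den
            new_lam[j] = float(np.clip(lam[j] * ratio, _LAM_MIN, _LAM_MAX))
        step = np.abs(np.log(new_lam) - np.log(lam)).max()
        lam = new_lam
        if step < 1e-3:
            break

    s_tot = total_penalty(lam)
    beta, eta, mu, dev = _pirls(xm, y, s_tot, eta)
    w = mu
    xtwx = (xm.T * w) @ xm
    h = xtwx + s_tot
    hinv = np.linalg.inv(h)
    edf_mat = hinv @ xtwx
    edf = float(np.trace(edf_mat))
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = max(pearson / max(n - edf, 1.0), 1e-8)
    edf_by_term = {
        name: float(np.trace(edf_mat[sl, sl])) for name, sl in zip(names, slices)
    }
    null_dev = _poisson_deviance(y, np.full(n, y.mean()))
    return GamFit(
        terms=terms,
        term_names=names,
        slices=slices,
        beta=beta,
        V_beta=phi * hinv,
        lambdas=lam,
        phi=phi,
        edf_total=edf,
        edf_by_term=edf_by_term,
        deviance=dev,
        null_deviance=null_dev,
        fitted=mu,
        has_spatial=coords is not None,
    )
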