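"""REML machinery for single- and multi-kernel linear mixed models.

The single-kernel model y = Xb + u + e, u ~ N(0, sg2 K), e ~ N(0, se2 I)
is fitted by spectral decomposition of K and a one-dimensional REML
search over the variance ratio lam = sg2/se2.  Multi-kernel fits
optimize the per-kernel ratios numerically with a Cholesky-based REML
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

_LOG_LAM_GRID = np.linspace(-8.0, 8.0, 33)
_SE2_FLOOR = 1e-10


@dataclass
class SpectralCache:
    eigvals: np.ndarray  # (n,)
    eigvecs: np.ndarray  # (n, n)


@dataclass
class LMMFit:
    """A fitted mixed model (REML).

    ``sigma2`` maps kernel names to variance components; ``'residual'``
    is always present.  ``reml_loglik`` is up to an additive constant.
    """

    beta: np.ndarray
    sigma2: dict[str, float]
    reml_loglik: float
    cache: SpectralCache | None = None
    extras: dict = field(default_factory=dict)

    @property
    def heritability_ratio(self) -> float:
        g = sum(v for k, v in self.sigma2.items() if k != "residual")
        tot = g + self.sigma2["residual"]
        return g / tot if tot > 0 else 0.0


def _reml_pieces(w, ys, Xs):
    """Weighted GLS pieces for rotated data with diagonal covariance w."""
    Xw = Xs / w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ys - Xs @ beta
    rss = float(resid @ (resid / w))
    return beta, XtWX, rss


def _reml_neg_ll(log_lam, d, ys, Xs):
    lam = np.exp(log_lam)
    w = lam * d + 1.0
    n, p = Xs.shape
    try:
        beta, XtWX, rss = _reml_pieces(w, ys, Xs)
    except np.linalg.LinAlgError:
        return np.inf
    rss = max(rss, _SE2_FLOOR)
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - p) * np.log(rss / (n - p)) + np.log(w).sum()
                 + logdet_x + (n - p))
    return -ll


def fit_single_kernel(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                      cache: SpectralCache | None = None,
                      kernel_name: str = "genetic") -> LMMFit:
    """REML fit of a single-kernel LMM via spectral decomposition."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(y).all():
        bad = np.flatnonzero(~np.isfinite(y))
        raise ValueError(f"non-finite phenotypes at rows {bad[:5].tolist()}")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    if cache is None:
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        cache = SpectralCache(d, U)
    d, U = cache.eigvals, cache.eigvecs
    ys = U.T @ y
    Xs = U.T @ X
    grid = [(_reml_neg_ll(ll, d, ys, Xs), ll) for ll in _LOG_LAM_GRID]
    _, best = min(grid)
    res = optimize.minimize_scalar(
        _reml_neg_ll, bounds=(best - 1.0, best + 1.0), args=(d, ys, Xs),
        method="bounded", options={"xatol": 1e-6})
    log_lam = res.x if res.fun <= _reml_neg_ll(best, d, ys, Xs) else best
    lam = float(np.exp(log_lam))
    w = lam * d + 1.0
    beta, XtWX, rss = _reml_pieces(w, ys, Xs)
    se2 = rss / (n - p)
    if se2 < _SE2_FLOOR:
        warnings.warn("residual variance hit its floor; phenotype may be "
                      "degenerate", stacklevel=2)
        se2 = _SE2_FLOOR
    sg2 = lam * se2
    ll = -float(res.fun if res.fun < np.inf else _reml_neg_ll(best, d, ys, Xs))
    return LMMFit(beta, {kernel_name: sg2, "residual": se2}, ll, cache,
                  extras={"lambda": lam})


def reml_neg_ll_cholesky(ratios: np.ndarray, y: np.ndarray, X: np.ndarray,
                         kernels: list[np.ndarray]) -> float:
    """-REML log-likelihood for V = se2 (sum_k ratio_k K_k + I)."""
    n, p = X.shape
    V = np.eye(n)
    for r, K in zip(ratios, kernels):
        V += r * K
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.log(np.diag(L)).sum()
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    rss = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    rss = max(rss, _SE2_FLOOR)
    return 0.5 * ((n - p) * np.log(rss / (n - p)) + logdet_v + logdet_x
                  + (n - p))


def fit_multi_kernel(y: np.ndarray, X: np.ndarray,
                     kernels: dict[str, np.ndarray]) -> LMMFit:
    """REML fit with several genetic kernels (numerical ratio search)."""
    names = list(kernels)
    mats = [np.asarray(kernels[k], dtype=float) for k in names]
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(mats) == 1:
        fit = fit_single_kernel(y, X, mats[0], kernel_name=names[0])
        return fit

    def obj(log_r):
        return reml_neg_ll_cholesky(np.exp(log_r), y, X, mats)

    starts = [np.zeros(len(mats)), np.full(len(mats), -2.0),
              np.array([0.0] + [-4.0] * (len(mats) - 1))]
    best = None
    for x0 in starts:
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    ratios = np.exp(best.x)
    V = np.eye(n)
    for r, K in zip(ratios, mats):
        V += r * K
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    rss = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    se2 = max(rss / (n - p), _SE2_FLOOR)
    sigma2 = {k: float(r * se2) for k, r in zip(names, ratios)}
    sigma2["residual"] = float(se2)
    return LMMFit(beta, sigma2, -float(best.fun), None,
                  extras={"ratios": dict(zip(names, ratios))})


def blup(fit: LMMFit, y: np.ndarray, X: np.ndarray,
         kernels_train: dict[str, np.ndarray],
         kernels_cross: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """BLUPs of each kernel's random effect for arbitrary individuals.

    ``kernels_train[k]`` is K_k among training individuals (n x n);
    ``kernels_cross[k]`` is K_k between target and training individuals
    (m x n).  Returns per-kernel effect vectors of length m.
    """
    n = len(y)
    se2 = fit.sigma2["residual"]
    V = se2 * np.eye(n)
    for k, Kt in kernels_train.items():
        V += fit.sigma2[k] * np.asarray(Kt)
    resid = np.asarray(y) - np.atleast_2d(X) @ fit.beta
    alpha = np.linalg.solve(V, resid)
    return {k: fit.sigma2[k] * (np.asarray(Kc) @ alpha)
            for k, Kc in kernels_cross.items()}
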