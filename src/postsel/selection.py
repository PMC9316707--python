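"""Lasso and adaptive-Lasso variable selection with penalty tuning.

The Lasso minimizes ``(1/2n) ||y - X b||^2 + lambda ||b||_1`` on a
standardized design with a centered outcome.  The adaptive Lasso replaces
the penalty with ``lambda * sum_j w_j |b_j|`` where the weights
``w_j = 1 / |b_hat_j,full|^gamma`` come from the unpenalized full model;
it is fitted by rescaling each column of X by ``1/w_j``, running the plain
Lasso, and back-transforming the coefficients.

Tuning rules: tenfold cross-validation at the minimum mean squared
prediction error, AIC/BIC with the active-set size as degrees of freedom,
or the fixed universal-threshold penalty
``lambda = c * sigma_hat * sqrt(2 log(p) / n)`` that does not use the
observed outcome beyond the supplied variance estimate.

The numerical workhorse is scikit-learn's coordinate descent
(:func:`sklearn.linear_model.lasso_path` / :class:`~sklearn.linear_model.Lasso`),
whose objective scaling matches the one above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.linear_model import Lasso
from sklearn.linear_model import lasso_path as _sk_lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "SelectionFit",
    "lambda_max",
    "lambda_path",
    "fit_lasso",
    "tune_lambda",
    "lambda_negahban",
    "lasso_fit",
    "adaptive_fit",
    "extract_active_set",
    "kkt_violation",
]

PATH_LENGTH = 100
PATH_MIN_RATIO = 1e-3
_CD_TOL = 1e-10


@dataclass
class SelectionFit:
    """Result of one selection stage.

    ``coefficients`` are on the standardized-X scale with exact zeros off
    the active set; ``weights`` are all ones for the plain Lasso and may be
    ``inf`` for variables excluded a priori by the adaptive weighting.
    """

    method: str            # "lasso" | "alasso"
    tuning: str            # "cv" | "aic" | "bic" | "neg" | "fixed"
    lam: float
    coefficients: np.ndarray
    active_set: tuple
    signs: np.ndarray
    weights: np.ndarray
    gamma: float = 0.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        coef = np.asarray(self.coefficients, dtype=float)
        if set(self.active_set) != set(np.flatnonzero(coef)):
            raise ValueError("coefficients outside the active set must be exactly zero")
        if not np.array_equal(self.signs, np.sign(coef[list(self.active_set)])):
            raise ValueError("signs inconsistent with coefficients")


def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must contain only finite values")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty with an all-zero solution: ``max_j |x_j'y| / n``."""
    return float(np.max(np.abs(X.T @ y)) / X.shape[0])


def lambda_path(X: np.ndarray, y: np.ndarray, length: int = PATH_LENGTH,
                min_ratio: float = PATH_MIN_RATIO) -> np.ndarray:
    """Log-spaced penalty grid from ``lambda_max`` down, decreasing."""
    lmax = lambda_max(X, y)
    if lmax <= 0:
        # y orthogonal to all columns; any positive grid keeps the model empty
        lmax = 1.0
    return np.geomspace(lmax, lmax * min_ratio, length)


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float, tol: float = _CD_TOL) -> np.ndarray:
    """Coordinate-descent minimizer of ``(1/2n)||y - Xb||^2 + lam ||b||_1``."""
    _check_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings surface via KKT checks
        model.fit(X, y)
    return model.coef_.copy()


def _path_coefs(X: np.ndarray, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """(p, n_alphas) coefficient path for a decreasing alpha grid."""
    # check_input=False skips sklearn's per-alpha validation, which would
    # otherwise dominate the runtime of CV tuning; it requires Fortran order.
    xf = np.asfortranarray(X, dtype=np.float64)
    yf = np.ascontiguousarray(y, dtype=np.float64)
    _, coefs, _ = _sk_lasso_path(xf, yf, alphas=alphas, tol=1e-8, max_iter=20_000,
                                 check_input=False)
    return coefs


@njit(cache=False)
def _gram_path(Q, q, alphas, tol, max_iter):  # pragma: no cover - compiled
    """Warm-started coordinate descent over a decreasing penalty grid.

    Solves ``min (1/2n)||y - Xb||^2 + alpha ||b||_1`` expressed through the
    Gram quantities ``Q = X'X/n`` and ``q = X'y/n``; used to scan the
    tuning path cheaply for the small designs this package targets.
    """
    p = q.shape[0]
    n_alphas = alphas.shape[0]
    coefs = np.zeros((p, n_alphas))
    b = np.zeros(p)
    grad = q.copy()                    # q - Q b
    for a_idx in range(n_alphas):
        alpha = alphas[a_idx]
        for _ in range(max_iter):
            delta_max = 0.0
            for j in range(p):
                qjj = Q[j, j]
                if qjj <= 0.0:
                    continue
                cj = grad[j] + qjj * b[j]
                if cj > alpha:
                    bj_new = (cj - alpha) / qjj
                elif cj < -alpha:
                    bj_new = (cj + alpha) / qjj
                else:
                    bj_new = 0.0
                diff = bj_new - b[j]
                if diff != 0.0:
                    for k in range(p):
                        grad[k] -= Q[k, j] * diff
                    b[j] = bj_new
                    if abs(diff) > delta_max:
                        delta_max = abs(diff)
            if delta_max < tol:
                break
        coefs[:, a_idx] = b
    return coefs


def tune_lambda(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "cv",
    n_folds: int = 10,
    seed: int = 0,
    path: np.ndarray | None = None,
) -> float:
    """Select a penalty from a log-spaced path by CV, AIC or BIC.

    Ties in the criterion are broken towards the smallest (densest) lambda.
    """
    _check_xy(X, y)
    if method not in ("cv", "aic", "bic"):
        raise ValueError(f"unknown tuning method {method!r}; use 'cv', 'aic' or 'bic'")
    n, _ = X.shape
    if path is None:
        path = lambda_path(X, y)
    path = np.asarray(path, dtype=float)
    if path.size == 1:
        return float(path[0])
    if np.any(np.diff(path) > 0):
        path = np.sort(path)[::-1]

    xtx = X.T @ X
    xty = X.T @ y
    if method == "cv":
        if n_folds > n:
            raise ValueError("n_folds may not exceed n")
        folds = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**32 - 1))
        sq_err = np.zeros(path.size)
        for train, test in folds.split(X):
            x_te, y_te = X[test], y[test]
            n_tr = train.size
            q_mat = (xtx - x_te.T @ x_te) / n_tr
            q_vec = (xty - x_te.T @ y_te) / n_tr
            coefs = _gram_path(q_mat, q_vec, path, 1e-9, 10_000)
            resid = y_te[:, None] - x_te @ coefs
            sq_err += np.sum(resid**2, axis=0)
        crit = sq_err / n
    else:
        coefs = _gram_path(xtx / n, xty / n, path, 1e-9, 10_000)
        rss = np.sum(y**2) - 2.0 * coefs.T @ xty + np.einsum("ja,jk,ka->a", coefs, xtx, coefs)
        df = np.count_nonzero(coefs, axis=0)
        k = 2.0 if method == "aic" else math.log(n)
        crit = n * np.log(np.maximum(rss, 1e-300) / n) + k * df

    best = np.flatnonzero(crit == crit.min())
    return float(path[best].min())


def lambda_negahban(p: int, n: int, sigma_hat: float, c: float = 2.0) -> float:
    """Fixed universal-threshold penalty ``c * sigma * sqrt(2 log(p) / n)``.

    Independent of the observed outcome except through the supplied
    variance estimate.
    """
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    if p < 2:
        warnings.warn("p < 2 gives log(p) = 0 and a zero penalty", stacklevel=2)
        logp = 0.0
    else:
        logp = math.log(p)
    return c * sigma_hat * math.sqrt(2.0 * logp / n)


def extract_active_set(coefficients, tol: float = 0.0) -> tuple[tuple, np.ndarray]:
    """Indices with ``|b_j| > tol`` in ascending order, with their signs."""
    coef = np.asarray(coefficients, dtype=float)
    active = tuple(int(j) for j in np.flatnonzero(np.abs(coef) > tol))
    signs = np.sign(coef[list(active)]) if active else np.array([])
    return active, signs


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    tuning: str | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionFit:
    """Plain Lasso selection with optional penalty tuning."""
    if lam is None:
        if tuning is None:
            raise ValueError("provide either lam or a tuning rule")
        lam = tune_lambda(X, y, tuning, n_folds=n_folds, seed=seed)
        label = tuning
    else:
        label = tuning or "fixed"
    coef = fit_lasso(X, y, lam)
    active, signs = extract_active_set(coef)
    return SelectionFit(
        method="lasso",
        tuning=label,
        lam=float(lam),
        coefficients=coef,
        active_set=active,
        signs=signs,
        weights=np.ones(X.shape[1]),
        gamma=0.0,
    )


def adaptive_fit(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float = 1.0,
    lam: float | None = None,
    tuning: str | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionFit:
    """Adaptive Lasso with full-model reciprocal-coefficient weights.

    Requires ``n > p`` so the unpenalized full model is estimable.  A full
    model coefficient of exactly zero yields an infinite weight; that
    variable is excluded a priori with a warning.
    """
    _check_xy(X, y)
    n, p = X.shape
    if n <= p:
        raise ValueError("adaptive weights require n > p")
    beta_full, *_ = np.linalg.lstsq(X, y, rcond=None)
    absb = np.abs(beta_full)
    included = absb > 0
    if not np.all(included):
        warnings.warn(
            f"full-model coefficients exactly zero for columns "
            f"{tuple(np.flatnonzero(~included))}; excluded a priori",
            stacklevel=2,
        )
    if not np.any(included):
        raise ValueError("all adaptive weights are infinite")
    weights = np.full(p, np.inf)
    weights[included] = 1.0 / absb[included] ** gamma
    cols = np.flatnonzero(included)
    x_scaled = X[:, cols] / weights[cols]

    if lam is None:
        if tuning is None:
            raise ValueError("provide either lam or a tuning rule")
        lam = tune_lambda(x_scaled, y, tuning, n_folds=n_folds, seed=seed)
        label = tuning
    else:
        label = tuning or "fixed"
    coef_scaled = fit_lasso(x_scaled, y, lam)
    coef = np.zeros(p)
    coef[cols] = coef_scaled / weights[cols]
    active, signs = extract_active_set(coef)
    return SelectionFit(
        method="alasso",
        tuning=label,
        lam=float(lam),
        coefficients=coef,
        active_set=active,
        signs=signs,
        weights=weights,
        gamma=float(gamma),
    )


def scaled_design(X: np.ndarray, fit: SelectionFit) -> tuple[np.ndarray, np.ndarray]:
    """Design on which ``fit`` is a plain-Lasso solution at ``fit.lam``.

    Returns ``(X_scaled, columns)`` where ``columns`` maps the scaled
    columns back to original indices (a priori excluded columns dropped).
    """
    cols = np.flatnonzero(np.isfinite(fit.weights))
    return X[:, cols] / fit.weights[cols], cols


def kkt_violation(X: np.ndarray, y: np.ndarray, coef: np.ndarray, lam: float) -> float:
    """Maximum violation of the Lasso stationarity conditions.

    Zero (to numerical tolerance) for an exact solution: the gradient
    ``x_j'(y - Xb)/n`` equals ``lam * sign(b_j)`` on the active set and is
    at most ``lam`` in absolute value elsewhere.
    """
    n = X.shape[0]
    grad = X.T @ (y - X @ coef) / n
    active = np.abs(coef) > 0
    v_active = np.abs(grad[active] - lam * np.sign(coef[active])).max(initial=0.0)
    v_inactive = np.maximum(np.abs(grad[~active]) - lam, 0.0).max(initial=0.0)
    return float(max(v_active, v_inactive))
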