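"""Confidence intervals for a selected linear submodel.

Four constructions are provided:

* classical Wald intervals (t-based with the submodel residual variance,
  or Gaussian with a plug-in variance estimate);
* sample splitting: select on one half, compute Wald t-intervals on the
  other half, yielding selective coverage by independence;
* exact post-selection inference (SI) conditional on the Lasso active set
  and sign pattern: the selection event is a polyhedron ``{A y <= b}``,
  so the law of a contrast ``eta'y`` given the selection (and the
  orthogonal component of ``y``) is a Gaussian truncated to an interval
  ``[V-, V+]``; confidence limits invert the truncated-Gaussian pivot;
* universally valid post-selection inference (PoSI): simultaneous
  intervals ``b_hat_{j,M} +/- K se(b_hat_{j,M})`` where the constant K
  bounds ``max_{M, j in M} |t_{j,M}|`` over *all* submodels at the
  requested level, approximated by Monte Carlo.

The outcome variance for SI and PoSI is estimated from the residuals of
the unpenalized full model, ``sigma2 = RSS_full / (n - p - 1)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtri
from scipy.stats import norm, t as t_dist

__all__ = [
    "IntervalSet",
    "TruncationInterval",
    "SplitResult",
    "InconsistentSelectionError",
    "estimate_sigma_full",
    "wald_ci",
    "split_inference",
    "lasso_selection_polyhedron",
    "si_truncation_interval",
    "si_ci",
    "posi_constant",
    "posi_ci",
]

# Numerics of the truncated-Gaussian pivot inversion (see docs/methods.md):
# bisection bracket of +/- 20 interval SDs around the observed contrast,
# absolute tolerance 1e-8 (scaled by the SD), at most 200 iterations, and
# truncation masses below 1e-12 treated as degenerate.
_BRACKET_SDS = 20.0
_BISECT_TOL = 1e-8
_BISECT_MAXIT = 200
_MIN_TRUNC_MASS = 1e-12
_LOG_MIN_MASS = math.log(_MIN_TRUNC_MASS)


class InconsistentSelectionError(ValueError):
    """The supplied (active set, signs) is not the Lasso solution for y."""


# ---------------------------------------------------------------------------
# Interval containers
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Per-variable point estimates and confidence limits for one method."""

    indices: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str
    level: float
    infinite_limit: np.ndarray = field(default=None)
    estimate_outside: np.ndarray = field(default=None)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        for name in ("estimate", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if np.any(self.lower > self.upper):
            raise ValueError("lower limit exceeds upper limit")
        if self.infinite_limit is None:
            self.infinite_limit = ~(np.isfinite(self.lower) & np.isfinite(self.upper))
        else:
            self.infinite_limit = np.asarray(self.infinite_limit, dtype=bool)
        expected_inf = ~(np.isfinite(self.lower) & np.isfinite(self.upper))
        if not np.array_equal(self.infinite_limit, expected_inf):
            raise ValueError("infinite_limit flags inconsistent with the limits")
        if self.estimate_outside is None:
            self.estimate_outside = (self.estimate < self.lower) | (self.estimate > self.upper)
        else:
            self.estimate_outside = np.asarray(self.estimate_outside, dtype=bool)

    @classmethod
    def empty(cls, method: str, level: float) -> "IntervalSet":
        z = np.array([])
        return cls(indices=z, estimate=z, lower=z, upper=z, method=method, level=level)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def unstable(self) -> bool:
        """Any interval with an infinite limit or excluding its estimate."""
        return bool(np.any(self.infinite_limit) or np.any(self.estimate_outside))


@dataclass
class TruncationInterval:
    """Values of a contrast compatible with a Lasso selection event."""

    v_minus: float
    v_plus: float

    def __post_init__(self):
        if self.v_minus > self.v_plus:
            raise ValueError("v_minus exceeds v_plus")


@dataclass
class SplitResult:
    """Half-B intervals plus the half-A selection and prediction pieces."""

    intervals: IntervalSet
    selected: tuple
    coefficients: np.ndarray   # half-B OLS embedded in a p-vector
    intercept: float
    dropped: tuple = ()


# ---------------------------------------------------------------------------
# Variance estimation and classical Wald intervals
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and (X'X)^{-1}; rejects rank-deficient designs."""
    xtx = X.T @ X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    return xtx_inv @ (X.T @ y), xtx_inv


def estimate_sigma_full(X: np.ndarray, y: np.ndarray) -> float:
    """Residual variance of the unpenalized full model, RSS / (n - p - 1).

    The extra degree of freedom accounts for the (centered-out) intercept.
    """
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 for a full-model variance estimate")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return rss / (n - p - 1)


def wald_ci(
    X_M: np.ndarray,
    y: np.ndarray,
    level: float,
    variance_mode: str = "t_df",
    sigma2: float | None = None,
    indices=None,
    method: str = "wald",
) -> IntervalSet:
    """Classical Wald intervals for the OLS fit on the submodel columns.

    ``t_df`` mode uses the submodel residual variance with
    ``df = n - |M| - 1``; ``plugin`` uses a supplied ``sigma2`` with
    Gaussian quantiles.
    """
    m = X_M.shape[1] if X_M.ndim == 2 else 0
    if indices is None:
        indices = np.arange(m)
    if m == 0:
        return IntervalSet.empty(method, level)
    n = X_M.shape[0]
    beta, xtx_inv = _ols(X_M, y)
    alpha = 1.0 - level
    if variance_mode == "t_df":
        df = n - m - 1
        if df < 1:
            raise ValueError("no residual degrees of freedom for t intervals")
        s2 = float(np.sum((y - X_M @ beta) ** 2)) / df
        q = t_dist.ppf(1.0 - alpha / 2.0, df)
    elif variance_mode == "plugin":
        if sigma2 is None:
            raise ValueError("plugin mode requires sigma2")
        s2 = float(sigma2)
        q = norm.ppf(1.0 - alpha / 2.0)
    else:
        raise ValueError("variance_mode must be 't_df' or 'plugin'")
    se = np.sqrt(s2 * np.diag(xtx_inv))
    return IntervalSet(
        indices=indices,
        estimate=beta,
        lower=beta - q * se,
        upper=beta + q * se,
        method=method,
        level=level,
    )


# ---------------------------------------------------------------------------
# Sample splitting
# ---------------------------------------------------------------------------

def split_inference(
    X: np.ndarray,
    y: np.ndarray,
    level: float,
    selector,
    split_seed,
) -> SplitResult:
    """Select on a random half A, compute Wald t-intervals on half B.

    ``selector(X_A, y_A)`` must return an object with an ``active_set``
    attribute.  With odd ``n`` half A receives the extra row.  Variables
    not estimable on half B (insufficient residual df or rank) are dropped
    with a flag rather than failing.
    """
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 to split")
    rng = split_seed if isinstance(split_seed, np.random.Generator) else np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    n_a = (n + 1) // 2
    rows_a, rows_b = perm[:n_a], perm[n_a:]
    y_a = y[rows_a] - y[rows_a].mean()
    fit = selector(X[rows_a], y_a)
    selected = tuple(fit.active_set)

    dropped: list[int] = []
    keep = list(selected)
    xb, yb = X[rows_b], y[rows_b]
    # drop from the back until the half-B OLS fit has df >= 1 and full rank
    while keep:
        if len(rows_b) - len(keep) - 1 >= 1 and np.linalg.matrix_rank(
            xb[:, keep] - xb[:, keep].mean(axis=0)
        ) == len(keep):
            break
        dropped.append(keep.pop())
    if dropped:
        warnings.warn(f"variables {tuple(dropped)} not estimable on half B; dropped",
                      stacklevel=2)
    if not keep:
        return SplitResult(
            intervals=IntervalSet.empty("split", level),
            selected=selected,
            coefficients=np.zeros(X.shape[1]),
            intercept=float(yb.mean()),
            dropped=tuple(dropped),
        )
    xb_m = xb[:, keep]
    xb_c = xb_m - xb_m.mean(axis=0)
    yb_c = yb - yb.mean()
    ivs = wald_ci(xb_c, yb_c, level, variance_mode="t_df",
                  indices=np.array(keep), method="split")
    coef = np.zeros(X.shape[1])
    coef[keep] = ivs.estimate
    intercept = float(yb.mean() - xb_m.mean(axis=0) @ ivs.estimate)
    return SplitResult(intervals=ivs, selected=selected, coefficients=coef,
                       intercept=intercept, dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# Exact post-selection inference (polyhedral / truncated Gaussian)
# ---------------------------------------------------------------------------

def lasso_selection_polyhedron(
    X: np.ndarray,
    lam: float,
    active_set,
    signs,
) -> tuple[np.ndarray, np.ndarray]:
    """Affine representation ``{y : A y <= b}`` of the event that the Lasso
    at penalty ``lam`` (objective scaled by 1/2n) selects ``active_set``
    with the given ``signs``.

    Rows encode (i) the active coefficients keeping their signs and
    (ii) the inactive subgradient staying in [-1, 1].
    """
    n, p = X.shape
    active = list(active_set)
    s = np.asarray(signs, dtype=float)
    inactive = [j for j in range(p) if j not in set(active)]
    lam_n = lam * n

    rows_a = []
    rows_b = []
    if active:
        xm = X[:, active]
        xtx_inv = np.linalg.inv(xm.T @ xm)
        pinv = xtx_inv @ xm.T                      # (m, n)
        rows_a.append(-(s[:, None] * pinv))
        rows_b.append(-lam_n * s * (xtx_inv @ s))
        proj = np.eye(n) - xm @ pinv
        cross = X[:, inactive].T @ xm @ xtx_inv @ s if inactive else None
    else:
        proj = np.eye(n)
        cross = np.zeros(len(inactive))
    if inactive:
        if lam_n <= 0:
            raise ValueError("an inactive set requires a positive penalty")
        g = X[:, inactive].T @ proj / lam_n        # (q, n)
        rows_a.extend([g, -g])
        rows_b.extend([1.0 - cross, 1.0 + cross])
    if not rows_a:
        return np.zeros((0, n)), np.zeros(0)
    return np.vstack(rows_a), np.concatenate(rows_b)


def si_truncation_interval(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    active_set,
    signs,
    eta: np.ndarray,
    kkt_tol: float = 1e-6,
) -> TruncationInterval:
    """Interval ``[V-, V+]`` of values of ``eta'y`` compatible with the
    selection event, holding the component of y orthogonal to eta fixed.

    With ``lam == 0`` the Lasso selects every variable for (almost) every
    outcome, so the selection event is unrestricted and the interval is
    the whole line.
    """
    if lam == 0:
        return TruncationInterval(-np.inf, np.inf)
    a, b = lasso_selection_polyhedron(X, lam, active_set, signs)
    slack = b - a @ y
    if np.any(slack < -kkt_tol * (1.0 + np.abs(b))):
        raise InconsistentSelectionError(
            "observed y violates the selection polyhedron; the supplied "
            "active set/signs do not satisfy the KKT conditions at lambda"
        )
    x_obs = float(eta @ y)
    c = eta / float(eta @ eta)
    ac = a @ c
    az = a @ y - ac * x_obs          # A z with z = y - c (eta'y)
    v_minus, v_plus = -np.inf, np.inf
    tol = 1e-12 * max(1.0, float(np.max(np.abs(ac))))
    neg = ac < -tol
    pos = ac > tol
    if np.any(neg):
        v_minus = float(np.max((b[neg] - az[neg]) / ac[neg]))
    if np.any(pos):
        v_plus = float(np.min((b[pos] - az[pos]) / ac[pos]))
    # guard against losing the observed value to roundoff
    v_minus = min(v_minus, x_obs)
    v_plus = max(v_plus, x_obs)
    return TruncationInterval(v_minus, v_plus)


def _log_diff(la: float, lb: float) -> float:
    """log(exp(la) - exp(lb)) for la >= lb."""
    if lb == -np.inf:
        return la
    d = lb - la
    if d >= 0.0:
        return -np.inf
    return la + math.log1p(-math.exp(d))


def _truncnorm_cdf(zx: float, za: float, zb: float) -> float:
    """CDF at ``zx`` of a standard Gaussian truncated to ``[za, zb]``.

    Evaluated through log CDFs or, by symmetry, log survival functions so
    that far-tail truncations keep full relative precision.  When the
    truncation mass falls below 1e-12 the distribution is treated as
    degenerate at the boundary nearest the mean.
    """
    if zx <= za:
        return 0.0
    if zx >= zb:
        return 1.0
    mid = 0.0
    if za > -np.inf and zb < np.inf:
        mid = 0.5 * (za + zb)
    elif zb < np.inf:
        mid = zb
    elif za > -np.inf:
        mid = za
    if mid > 0.0:
        return 1.0 - _truncnorm_cdf(-zx, -zb, -za)
    l_den = _log_diff(log_ndtr(zb), log_ndtr(za))
    if l_den < _LOG_MIN_MASS:
        # mass concentrates at the upper boundary (the one nearest 0 here)
        return 0.0 if zx < zb else 1.0
    l_num = _log_diff(log_ndtr(zx), log_ndtr(za))
    return min(1.0, math.exp(l_num - l_den))


def _pivot(mu: float, x: float, sd: float, v_minus: float, v_plus: float) -> float:
    return _truncnorm_cdf((x - mu) / sd, (v_minus - mu) / sd, (v_plus - mu) / sd)


def _invert_pivot(
    target: float, x: float, sd: float, v_minus: float, v_plus: float
) -> float:
    """Solve ``F(x; mu) = target`` for mu by bisection.

    The pivot is nonincreasing in mu.  Returns ``+/- inf`` when no root
    lies within ``x +/- 20 sd``.
    """
    lo, hi = x - _BRACKET_SDS * sd, x + _BRACKET_SDS * sd
    f_lo = _pivot(lo, x, sd, v_minus, v_plus)
    f_hi = _pivot(hi, x, sd, v_minus, v_plus)
    if f_lo < target:
        return -np.inf
    if f_hi > target:
        return np.inf
    for _ in range(_BISECT_MAXIT):
        mid = 0.5 * (lo + hi)
        if _pivot(mid, x, sd, v_minus, v_plus) >= target:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL * max(sd, 1.0):
            break
    return 0.5 * (lo + hi)


def si_ci(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    active_set,
    signs,
    sigma2: float,
    level: float,
    X_inference: np.ndarray | None = None,
    active_inference=None,
) -> IntervalSet:
    """Selective CIs for the submodel OLS coefficients after Lasso selection.

    The polyhedron is built on the *selection* design ``X`` (for the
    adaptive Lasso this is the weight-rescaled design), while the contrast,
    point estimate and reported indices come from ``X_inference`` (defaults
    to ``X``).  Limits the pivot cannot reach within the bisection bracket
    are reported as infinite with the corresponding flag.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if X_inference is None:
        X_inference = X
    if active_inference is None:
        active_inference = tuple(active_set)
    active_inference = tuple(active_inference)
    if len(active_inference) == 0:
        return IntervalSet.empty("si", level)
    xm = X_inference[:, list(active_inference)]
    beta, xtx_inv = _ols(xm, y)
    contrasts = xm @ xtx_inv                      # columns are the eta_j
    alpha = 1.0 - level
    lower = np.empty(len(active_inference))
    upper = np.empty(len(active_inference))
    for k in range(len(active_inference)):
        eta = contrasts[:, k]
        trunc = si_truncation_interval(X, y, lam, active_set, signs, eta)
        x_obs = float(eta @ y)
        sd = math.sqrt(sigma2 * float(eta @ eta))
        lower[k] = _invert_pivot(1.0 - alpha / 2.0, x_obs, sd, trunc.v_minus, trunc.v_plus)
        upper[k] = _invert_pivot(alpha / 2.0, x_obs, sd, trunc.v_minus, trunc.v_plus)
        if lower[k] > upper[k]:                   # numerically crossed: widen to flag
            lower[k], upper[k] = upper[k], lower[k]
    return IntervalSet(
        indices=np.array(active_inference),
        estimate=beta,
        lower=lower,
        upper=upper,
        method="si",
        level=level,
    )


def flag_extreme_widths(intervals: IntervalSet, reference: IntervalSet,
                        ratio: float = 100.0) -> np.ndarray:
    """Optional width-ratio alarm: flags intervals wider than ``ratio``
    times the matching reference (plug-in Wald) interval.

    Not part of the default unstable-CI definition; provided for users who
    want a stricter stability screen.
    """
    ref = dict(zip(reference.indices.tolist(), reference.width))
    flags = np.zeros(len(intervals), dtype=bool)
    for k, j in enumerate(intervals.indices):
        w_ref = ref.get(int(j))
        if w_ref is not None and w_ref > 0:
            flags[k] = intervals.width[k] > ratio * w_ref
    return flags


# ---------------------------------------------------------------------------
# Universally valid post-selection inference (PoSI)
# ---------------------------------------------------------------------------

def posi_constant(
    X: np.ndarray,
    level: float,
    max_p_exact: int = 12,
    n_mc: int = 5000,
    seed=0,
    max_models: int = 4096,
    df: int | None = None,
) -> float:
    """Monte-Carlo PoSI multiplier K for the design ``X``.

    Smallest K with estimated
    ``P(max over nonempty M subset M_F, j in M of |t_{j,M}| <= K) >= level``
    where ``t_{j,M}`` is the standardized OLS coefficient statistic of j in
    submodel M under a common Gaussian error draw.  All ``2^p - 1``
    submodels are enumerated for ``p <= max_p_exact``; beyond that a random
    subsample of ``max_models`` models is used with a warning.

    With ``df`` given, each draw's maximum is divided by an independent
    ``sqrt(chi2_df / df)`` — the simultaneous-t reference appropriate when
    the plugged-in variance is itself estimated on ``df`` degrees of
    freedom; ``df=None`` keeps the Gaussian (known-variance) reference.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # work in the p-dimensional column space: X = Q R, errors project to
    # independent standard normals in the Q basis
    q_mat, r_mat = np.linalg.qr(X)
    models: list[tuple] = []
    if p <= max_p_exact:
        for size in range(1, p + 1):
            models.extend(itertools.combinations(range(p), size))
    else:
        warnings.warn(
            f"p = {p} > {max_p_exact}: approximating the PoSI constant on a "
            f"random subsample of {max_models} submodels",
            stacklevel=2,
        )
        full = tuple(range(p))
        seen = {full}
        models.append(full)
        while len(models) < max_models:
            size = int(rng.integers(1, p + 1))
            m = tuple(sorted(rng.choice(p, size=size, replace=False)))
            if m not in seen:
                seen.add(m)
                models.append(m)
    rows = []
    for m in models:
        rm = r_mat[:, list(m)]
        hinv = np.linalg.inv(rm.T @ rm)
        block = hinv @ rm.T                       # (|M|, p)
        block /= np.sqrt(np.diag(hinv))[:, None]  # unit-norm rows
        rows.append(block)
    l_mat = np.vstack(rows)                       # (sum |M|, p)
    z = rng.standard_normal((n_mc, p))
    maxima = np.max(np.abs(z @ l_mat.T), axis=1)
    if df is not None:
        if df < 1:
            raise ValueError("df must be positive")
        maxima = maxima / np.sqrt(rng.chisquare(df, size=n_mc) / df)
    maxima.sort()
    k_idx = min(n_mc - 1, max(0, math.ceil(level * n_mc) - 1))
    return float(maxima[k_idx])


def posi_ci(
    X_M: np.ndarray,
    y: np.ndarray,
    K: float,
    sigma2: float,
    df: int | None = None,
    indices=None,
    level: float = 0.90,
) -> IntervalSet:
    """Simultaneous intervals ``b_hat_{j,M} +/- K se(b_hat_{j,M})``.

    Standard errors use the full-model variance estimate ``sigma2`` with a
    Gaussian reference; ``df`` is recorded for context but unused by
    default.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    m = X_M.shape[1] if X_M.ndim == 2 else 0
    if indices is None:
        indices = np.arange(m)
    if m == 0:
        return IntervalSet.empty("posi", level)
    beta, xtx_inv = _ols(X_M, y)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return IntervalSet(
        indices=np.asarray(indices, dtype=int),
        estimate=beta,
        lower=beta - K * se,
        upper=beta + K * se,
        method="posi",
        level=level,
    )
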