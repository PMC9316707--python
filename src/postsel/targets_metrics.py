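"""Submodel inference targets and simulation performance measures.

The inference target for a selected submodel M is the population
projection ``beta_M = Sigma_MM^{-1} Sigma_{M,F} beta`` — the coefficients
of the best linear approximation to the full model using only the
variables in M.  It is not meant to recover the full-model beta unless
the predictors are uncorrelated.

Performance measures marginalize over selected models and variables:
selective coverage / power / type-1 error are computed over selected
(variable, iteration) pairs, CI widths are pooled with infinite-width
intervals excluded from the median/IQR but counted into the unstable
rate, and selection quality is summarized by the true-model probability
and per-variable selection frequencies.  Predictive accuracy is the R^2
achieved on an independent validation outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .inference import IntervalSet

__all__ = [
    "SubmodelTarget",
    "MethodResult",
    "submodel_target",
    "selective_metrics",
    "width_stability_summary",
    "selection_metrics",
    "validation_r2",
]

TARGET_ZERO_TOL = 1e-12


@dataclass
class SubmodelTarget:
    """Population projection coefficients for a fixed submodel."""

    model: tuple
    values: np.ndarray

    def __post_init__(self):
        self.model = tuple(int(j) for j in self.model)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.model):
            raise ValueError("target length does not match the model")


@dataclass
class MethodResult:
    """One method's outcome in one simulation iteration."""

    method: str
    selected: tuple = ()
    intervals: IntervalSet | None = None
    target: SubmodelTarget | None = None
    coefficients: np.ndarray | None = None  # prediction coefficients, length p
    intercept: float = 0.0
    valid_r2: float = math.nan
    lam: float = math.nan
    failed: bool = False
    error: str = ""


def submodel_target(Sigma: np.ndarray, beta, M) -> SubmodelTarget:
    """``beta_M = Sigma_MM^{-1} Sigma_{M, M_F} beta`` for the submodel M."""
    model = tuple(int(j) for j in M)
    beta = np.asarray(beta, dtype=float)
    if not model:
        return SubmodelTarget(model=(), values=np.array([]))
    idx = list(model)
    smm = Sigma[np.ix_(idx, idx)]
    smf = Sigma[idx, :]
    try:
        values = np.linalg.solve(smm, smf @ beta)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"Sigma submatrix for model {model} is singular") from exc
    if not np.all(np.isfinite(values)) or np.linalg.cond(smm) > 1e12:
        raise ValueError(f"Sigma submatrix for model {model} is (near) singular")
    return SubmodelTarget(model=model, values=values)


def _pairs(results):
    """Yield (target, lower, upper) per selected variable across results."""
    for res in results:
        if res.failed or res.intervals is None or len(res.intervals) == 0:
            continue
        if res.target is None:
            raise ValueError("interval set without a matching target")
        tmap = dict(zip(res.target.model, res.target.values))
        for k, j in enumerate(res.intervals.indices):
            if int(j) not in tmap:
                raise ValueError("interval index outside the target model")
            yield tmap[int(j)], res.intervals.lower[k], res.intervals.upper[k]


def selective_metrics(results, zero_tol: float = TARGET_ZERO_TOL) -> dict:
    """Selective coverage, power and type-1 error with their denominators.

    Rates are over selected (variable, iteration) pairs; power counts
    pairs with a nonzero submodel target, type-1 error pairs with a zero
    target.  Undefined rates (zero denominator) are reported as NaN.
    """
    cov_num = cov_den = pow_num = pow_den = t1_num = t1_den = 0
    for target, lo, hi in _pairs(results):
        cov_den += 1
        if lo <= target <= hi:
            cov_num += 1
        excludes_zero = (lo > 0.0) or (hi < 0.0)
        if abs(target) < zero_tol:
            t1_den += 1
            t1_num += excludes_zero
        else:
            pow_den += 1
            pow_num += excludes_zero
    rate = lambda a, b: a / b if b else math.nan
    return {
        "coverage": rate(cov_num, cov_den),
        "coverage_n": cov_den,
        "power": rate(pow_num, pow_den),
        "power_n": pow_den,
        "type1": rate(t1_num, t1_den),
        "type1_n": t1_den,
    }


def width_stability_summary(results) -> dict:
    """Pooled CI width median/IQR and the unstable-iteration rate.

    Infinite-width intervals are excluded from the width summaries but
    every iteration with an infinite limit or an interval excluding its
    point estimate counts as unstable.  The denominator is the number of
    iterations with a nonempty selection.
    """
    widths: list[float] = []
    n_nonempty = 0
    n_unstable = 0
    for res in results:
        if res.failed or res.intervals is None or len(res.intervals) == 0:
            continue
        n_nonempty += 1
        if res.intervals.unstable:
            n_unstable += 1
        w = res.intervals.width
        widths.extend(w[np.isfinite(w)].tolist())
    out = {
        "width_median": math.nan,
        "width_iqr": math.nan,
        "width_n": len(widths),
        "unstable_rate": (n_unstable / n_nonempty) if n_nonempty else math.nan,
        "unstable_n": n_nonempty,
    }
    if widths:
        arr = np.asarray(widths)
        q25, q50, q75 = np.percentile(arr, [25, 50, 75])
        out["width_median"] = float(q50)
        out["width_iqr"] = float(q75 - q25)
    return out


def selection_metrics(results, beta_true) -> dict:
    """True-model selection probability and per-variable frequencies."""
    beta_true = np.asarray(beta_true, dtype=float)
    p = beta_true.size
    true_model = tuple(int(j) for j in np.flatnonzero(beta_true))
    n_ok = 0
    n_true = 0
    freq = np.zeros(p)
    for res in results:
        if res.failed:
            continue
        n_ok += 1
        sel = tuple(res.selected)
        if sel == true_model:
            n_true += 1
        for j in sel:
            freq[j] += 1
    return {
        "true_model_prob": (n_true / n_ok) if n_ok else math.nan,
        "selection_freq": (freq / n_ok) if n_ok else np.full(p, math.nan),
        "selection_n": n_ok,
    }


def validation_r2(X: np.ndarray, coefficients, y_valid: np.ndarray,
                  intercept: float = 0.0) -> float:
    """``1 - RSS / TSS`` of the prediction ``intercept + X b`` on fresh data."""
    coefficients = np.asarray(coefficients, dtype=float)
    pred = intercept + X @ coefficients
    tss = float(np.sum((y_valid - y_valid.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("validation outcome has zero variance")
    rss = float(np.sum((y_valid - pred) ** 2))
    return 1.0 - rss / tss
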