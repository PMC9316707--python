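"""Run the factorial simulation grid for all selection/inference methods.

Each iteration draws one dataset, applies every configured method (a
selection stage followed by an inference stage), computes the submodel
target for the model that was actually selected, and records the
intervals, flags and validation R^2.  Scenario-level summaries aggregate
the iteration records into selective coverage / power / type-1 error,
width and stability summaries, selection metrics, and a binomial
Monte-Carlo error band for the nominal level.

Randomness is organized so that results are reproducible regardless of
worker count: every random stream is seeded by
``SeedSequence([master_seed, scenario_index, iteration_index, stream])``
with a named substream per purpose (data, CV folds for each selector,
the split permutation, the PoSI Monte Carlo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import inference, selection
from .synthetic_data import (
    ScenarioConfig,
    build_correlation_matrix,
    generate_design,
    generate_outcomes,
    scenario_noise_sd,
    toy_grid,
)
from .targets_metrics import (
    MethodResult,
    selection_metrics,
    selective_metrics,
    submodel_target,
    validation_r2,
    width_stability_summary,
)

__all__ = [
    "METHOD_ROSTER",
    "GridConfig",
    "run_iteration",
    "run_scenario",
    "run_grid",
    "desk_toy_scenarios",
    "mc_band_halfwidth",
]

METHOD_ROSTER = (
    "Full",
    "Oracle",
    "Lasso-CV-Split",
    "Lasso-CV-PoSI",
    "Lasso-CV-SI",
    "Lasso-Neg-SI",
    "ALasso-CV-Split",
    "ALasso-CV-PoSI",
    "ALasso-CV-SI",
    "ALasso-Neg-SI",
)

# named substreams of the per-iteration seed
_STREAM_DATA = 0
_STREAM_LASSO_FOLDS = 1
_STREAM_ALASSO_FOLDS = 2
_STREAM_SPLIT_PERM = 3
_STREAM_SPLIT_FOLDS = 4
_STREAM_POSI = 5

POSI_MC_DRAWS = 5000
NEGAHBAN_C = 2.0
ADAPTIVE_GAMMA = 1.0


@dataclass(frozen=True)
class GridConfig:
    """Scenario list, method roster and execution parameters for a run."""

    scenarios: tuple
    roster: tuple = METHOD_ROSTER
    n_iterations: int | None = None   # overrides each scenario's count
    master_seed: int = 0
    workers: int = 1
    posi_mc: int = POSI_MC_DRAWS

    def __post_init__(self):
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "roster", tuple(self.roster))
        unknown = [m for m in self.roster if m not in METHOD_ROSTER]
        if unknown:
            raise ValueError(
                f"unknown method labels {unknown}; valid labels: {METHOD_ROSTER}"
            )
        if not self.roster:
            raise ValueError("roster may not be empty")


def _stream(master_seed: int, scenario_idx: int, iter_idx: int, stream: int):
    ss = np.random.SeedSequence([int(master_seed), int(scenario_idx), int(iter_idx), int(stream)])
    return np.random.default_rng(ss)


def _fold_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def apply_method(
    label: str,
    X: np.ndarray,
    y: np.ndarray,
    level: float,
    seeds: dict,
    sigma2: float | None = None,
    cache: dict | None = None,
    oracle_model: tuple | None = None,
    posi_mc: int = POSI_MC_DRAWS,
) -> MethodResult:
    """Run one method's selection and inference stages on a dataset.

    ``seeds`` maps ``{"folds_lasso", "folds_alasso", "split", "split_folds",
    "posi"}`` to integers or Generators.  ``cache`` (shared across methods
    of the same iteration) avoids refitting shared stages: the CV-tuned
    Lasso/ALasso fits, the full-model variance and the PoSI constant.
    ``y`` is centered internally; prediction coefficients refer to the
    standardized design with the returned intercept.
    """
    if cache is None:
        cache = {}
    n, p = X.shape
    y_mean = float(np.mean(y))
    yc = y - y_mean

    def sigma2_full() -> float:
        if "sigma2" not in cache:
            cache["sigma2"] = sigma2 if sigma2 is not None else inference.estimate_sigma_full(X, yc)
        return cache["sigma2"]

    def lasso_cv() -> selection.SelectionFit:
        if "lasso_cv" not in cache:
            cache["lasso_cv"] = selection.lasso_fit(
                X, yc, tuning="cv", seed=seeds["folds_lasso"])
        return cache["lasso_cv"]

    def alasso_cv() -> selection.SelectionFit:
        if "alasso_cv" not in cache:
            cache["alasso_cv"] = selection.adaptive_fit(
                X, yc, gamma=ADAPTIVE_GAMMA, tuning="cv", seed=seeds["folds_alasso"])
        return cache["alasso_cv"]

    def neg_fit(adaptive: bool) -> selection.SelectionFit:
        key = "alasso_neg" if adaptive else "lasso_neg"
        if key not in cache:
            lam = selection.lambda_negahban(p, n, math.sqrt(sigma2_full()), NEGAHBAN_C)
            if adaptive:
                cache[key] = selection.adaptive_fit(X, yc, gamma=ADAPTIVE_GAMMA, lam=lam,
                                                    tuning="neg")
            else:
                cache[key] = selection.lasso_fit(X, yc, lam=lam, tuning="neg")
        return cache[key]

    def posi_k() -> float:
        # simultaneous-t reference: sigma2 comes from the full model on
        # n - p - 1 degrees of freedom
        if "posi_k" not in cache:
            cache["posi_k"] = inference.posi_constant(
                X, level, n_mc=posi_mc, seed=seeds["posi"], df=n - p - 1)
        return cache["posi_k"]

    if label == "Full":
        ivs = inference.wald_ci(X, yc, level, variance_mode="t_df",
                                indices=np.arange(p), method="wald")
        return MethodResult(method=label, selected=tuple(range(p)), intervals=ivs,
                            coefficients=ivs.estimate.copy(), intercept=y_mean)

    if label == "Oracle":
        if oracle_model is None:
            raise ValueError("the Oracle method requires the true model")
        model = tuple(oracle_model)
        if not model:
            return MethodResult(
                method=label, selected=(), intervals=inference.IntervalSet.empty("wald", level),
                coefficients=np.zeros(p), intercept=y_mean)
        ivs = inference.wald_ci(X[:, list(model)], yc, level, variance_mode="t_df",
                                indices=np.array(model), method="wald")
        coef = np.zeros(p)
        coef[list(model)] = ivs.estimate
        return MethodResult(method=label, selected=model, intervals=ivs,
                            coefficients=coef, intercept=y_mean)

    if label.endswith("-Split"):
        adaptive = label.startswith("ALasso")
        fold_seed = seeds["split_folds"]

        def selector(xa, ya):
            if adaptive:
                return selection.adaptive_fit(xa, ya, gamma=ADAPTIVE_GAMMA,
                                              tuning="cv", seed=fold_seed)
            return selection.lasso_fit(xa, ya, tuning="cv", seed=fold_seed)

        res = inference.split_inference(X, y, level, selector, seeds["split"])
        return MethodResult(method=label, selected=res.selected, intervals=res.intervals,
                            coefficients=res.coefficients, intercept=res.intercept)

    adaptive = label.startswith("ALasso")
    if "-CV-" in label:
        fit = alasso_cv() if adaptive else lasso_cv()
    elif "-Neg-" in label:
        fit = neg_fit(adaptive)
    else:
        raise ValueError(f"unknown method label {label!r}")
    selected = fit.active_set
    coef_pred = fit.coefficients.copy()

    if label.endswith("-PoSI"):
        if not selected:
            ivs = inference.IntervalSet.empty("posi", level)
        else:
            ivs = inference.posi_ci(X[:, list(selected)], yc, posi_k(), sigma2_full(),
                                    df=n - p - 1, indices=np.array(selected), level=level)
        return MethodResult(method=label, selected=selected, intervals=ivs,
                            coefficients=coef_pred, intercept=y_mean, lam=fit.lam)

    if label.endswith("-SI"):
        if not selected:
            ivs = inference.IntervalSet.empty("si", level)
        else:
            x_sel, cols = selection.scaled_design(X, fit)
            pos = {int(j): k for k, j in enumerate(cols)}
            active_scaled = tuple(pos[j] for j in selected)
            ivs = inference.si_ci(
                x_sel, yc, fit.lam, active_scaled, fit.signs, sigma2_full(), level,
                X_inference=X, active_inference=selected)
        return MethodResult(method=label, selected=selected, intervals=ivs,
                            coefficients=coef_pred, intercept=y_mean, lam=fit.lam)

    raise ValueError(f"unknown method label {label!r}")


@dataclass
class _ScenarioState:
    """Per-scenario quantities that do not change across iterations."""

    corr: np.ndarray
    Sigma: np.ndarray
    noise_sd: float
    oracle_model: tuple


def _prepare_scenario(scenario: ScenarioConfig) -> _ScenarioState:
    corr = build_correlation_matrix(scenario.correlation)
    # one throwaway draw resolves the (cached) population covariance
    _, sigma_mat = generate_design(corr, scenario.transforms, max(scenario.n, 2), 0)
    noise_sd = scenario_noise_sd(scenario, sigma_mat)
    beta = np.asarray(scenario.beta)
    return _ScenarioState(
        corr=corr,
        Sigma=sigma_mat,
        noise_sd=noise_sd,
        oracle_model=tuple(int(j) for j in np.flatnonzero(beta)),
    )


def run_iteration(
    scenario: ScenarioConfig,
    roster,
    master_seed: int,
    scenario_idx: int,
    iter_idx: int,
    state: _ScenarioState | None = None,
    posi_mc: int = POSI_MC_DRAWS,
) -> list[MethodResult]:
    """One data draw and one :class:`MethodResult` per roster method.

    A failing method is caught and recorded as failed; it never aborts the
    iteration.
    """
    roster = tuple(roster)
    if not roster:
        raise ValueError("roster may not be empty")
    unknown = [m for m in roster if m not in METHOD_ROSTER]
    if unknown:
        raise ValueError(f"unknown method label(s) {unknown}; valid: {METHOD_ROSTER}")
    if state is None:
        state = _prepare_scenario(scenario)
    rng_data = _stream(master_seed, scenario_idx, iter_idx, _STREAM_DATA)
    x, _ = generate_design(state.corr, scenario.transforms, scenario.n, rng_data)
    y, y_valid = generate_outcomes(x, scenario.beta, state.noise_sd, rng_data)
    seeds = {
        "folds_lasso": _fold_seed(_stream(master_seed, scenario_idx, iter_idx, _STREAM_LASSO_FOLDS)),
        "folds_alasso": _fold_seed(_stream(master_seed, scenario_idx, iter_idx, _STREAM_ALASSO_FOLDS)),
        "split": _stream(master_seed, scenario_idx, iter_idx, _STREAM_SPLIT_PERM),
        "split_folds": _fold_seed(_stream(master_seed, scenario_idx, iter_idx, _STREAM_SPLIT_FOLDS)),
        "posi": _stream(master_seed, scenario_idx, iter_idx, _STREAM_POSI),
    }
    cache: dict = {}
    results = []
    for label in roster:
        try:
            res = apply_method(label, x, y, scenario.confidence_level, seeds,
                               cache=cache, oracle_model=state.oracle_model,
                               posi_mc=posi_mc)
            res.target = submodel_target(state.Sigma, scenario.beta, res.selected)
            res.valid_r2 = validation_r2(x, res.coefficients, y_valid, res.intercept)
        except Exception as exc:  # record, do not abort the iteration
            res = MethodResult(method=label, failed=True, error=f"{type(exc).__name__}: {exc}")
        results.append(res)
    return results


def mc_band_halfwidth(level: float, n_iterations: int) -> float:
    """Half-width of the binomial 95% Monte-Carlo band at the nominal level."""
    return 1.96 * math.sqrt(level * (1.0 - level) / n_iterations)


def run_scenario(
    scenario: ScenarioConfig,
    roster=METHOD_ROSTER,
    master_seed: int = 0,
    scenario_idx: int = 0,
    n_iterations: int | None = None,
    posi_mc: int = POSI_MC_DRAWS,
    collect_results: bool = False,
):
    """Aggregate ``n_iterations`` records into one summary row per method."""
    n_iter = n_iterations if n_iterations is not None else scenario.n_iterations
    if n_iter < 1:
        raise ValueError("n_iterations must be positive")
    state = _prepare_scenario(scenario)
    per_method: dict[str, list[MethodResult]] = {m: [] for m in roster}
    for it in range(n_iter):
        for res in run_iteration(scenario, roster, master_seed, scenario_idx, it,
                                 state=state, posi_mc=posi_mc):
            per_method[res.method].append(res)

    rows = []
    band = mc_band_halfwidth(scenario.confidence_level, n_iter)
    for label in roster:
        results = per_method[label]
        n_failed = sum(r.failed for r in results)
        row = {
            "scenario": scenario.name,
            "scenario_idx": scenario_idx,
            "method": label,
            "level": scenario.confidence_level,
            "n_iterations": n_iter,
            "n_failed": n_failed,
            "mc_band_halfwidth": band,
        }
        row.update(selective_metrics(results))
        row.update(width_stability_summary(results))
        sel = selection_metrics(results, np.asarray(scenario.beta))
        row["true_model_prob"] = sel["true_model_prob"]
        row["selection_n"] = sel["selection_n"]
        for j, f in enumerate(sel["selection_freq"]):
            row[f"sel_freq_{j}"] = f
        r2s = [r.valid_r2 for r in results if not r.failed and np.isfinite(r.valid_r2)]
        row["valid_r2_mean"] = float(np.mean(r2s)) if r2s else math.nan
        rows.append(row)
    if collect_results:
        return rows, per_method
    return rows


def run_grid(config: GridConfig) -> pd.DataFrame:
    """One summary row per scenario x method, deterministic in the master seed.

    Seeds are assigned by scenario and iteration index, so the result is
    invariant to the worker count.
    """
    tasks = [
        delayed(run_scenario)(
            scenario,
            roster=config.roster,
            master_seed=config.master_seed,
            scenario_idx=i,
            n_iterations=config.n_iterations,
            posi_mc=config.posi_mc,
        )
        for i, scenario in enumerate(config.scenarios)
    ]
    if config.workers == 1:
        chunks = [t[0](*t[1], **t[2]) for t in tasks]
    else:
        chunks = Parallel(n_jobs=config.workers)(tasks)
    rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(rows)


def desk_toy_scenarios(stride: int = 10, n_iterations: int = 200,
                       confidence_level: float = 0.90) -> list[ScenarioConfig]:
    """Systematic 1-in-``stride`` subsample of the 630-scenario toy grid.

    The desk-scale profile used for quick full-pipeline runs: with the
    default stride it keeps 63 scenarios spread over all correlation and
    coefficient structures.
    """
    return toy_grid(n_iterations=n_iterations,
                    confidence_level=confidence_level)[::stride]
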