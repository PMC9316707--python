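"""Interval constructions: Wald, sample splitting, polyhedral SI, PoSI."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from postsel.inference import (
    InconsistentSelectionError,
    IntervalSet,
    estimate_sigma_full,
    posi_ci,
    posi_constant,
    si_ci,
    si_truncation_interval,
    split_inference,
    wald_ci,
)
from postsel.selection import extract_active_set, fit_lasso, lasso_fit
from postsel.targets_metrics import submodel_target
from conftest import standardized_design


class TestSigmaFull:
    def test_perfect_fit_gives_zero(self, rng):
        x = standardized_design(rng, 20, 3)
        y = x @ np.array([1.0, -2.0, 0.5])
        assert estimate_sigma_full(x, y) == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        rss = np.sum((y - x @ beta) ** 2)
        assert estimate_sigma_full(x, y) == pytest.approx(rss / (10 - 2 - 1))

    def test_unbiased_over_replicates(self):
        rng = np.random.default_rng(5)
        x = standardized_design(rng, 30, 4)
        vals = []
        for _ in range(2000):
            y = x[:, 0] + 1.5 * rng.standard_normal(30)
            vals.append(estimate_sigma_full(x, y - y.mean()))
        assert abs(np.mean(vals) - 2.25) / 2.25 < 0.02

    def test_insufficient_df_rejected(self, rng):
        with pytest.raises(ValueError, match="n > p"):
            estimate_sigma_full(rng.standard_normal((4, 3)), rng.standard_normal(4))


class TestWaldCI:
    def test_empty_model_gives_empty_set(self, rng):
        ivs = wald_ci(np.empty((10, 0)), rng.standard_normal(10), 0.9)
        assert len(ivs) == 0

    def test_plugin_width_scales_with_sigma(self, small_xy):
        x, y = small_xy
        a = wald_ci(x, y, 0.9, variance_mode="plugin", sigma2=1.0)
        b = wald_ci(x, y, 0.9, variance_mode="plugin", sigma2=4.0)
        assert np.allclose(b.width, 2.0 * a.width)

    def test_t_coverage_at_nominal_level(self):
        # classical 90% t-intervals cover the design-based target
        rng = np.random.default_rng(77)
        x = standardized_design(rng, 25, 3)
        beta = np.array([1.0, 0.0, -0.5])
        mu = x @ beta
        target = np.linalg.solve(x.T @ x, x.T @ mu)
        n_rep = 2000
        # per-variable marginal coverage within 3 binomial SE of 0.90
        hits = np.zeros(3)
        for _ in range(n_rep):
            y = mu + rng.standard_normal(25)
            ivs = wald_ci(x, y - y.mean(), 0.90)
            hits += (ivs.lower <= target) & (target <= ivs.upper)
        se = np.sqrt(0.9 * 0.1 / n_rep)
        assert np.all(np.abs(hits / n_rep - 0.90) < 3 * se)

    def test_interval_set_flag_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            IntervalSet(
                indices=[0], estimate=[1.0], lower=[0.0], upper=[2.0],
                method="wald", level=0.9, infinite_limit=[True],
            )


class TestSplitInference:
    def test_empty_selection_gives_empty_intervals(self, rng):
        x = standardized_design(rng, 20, 3)
        y = rng.standard_normal(20)

        class NullFit:
            active_set = ()

        res = split_inference(x, y, 0.9, lambda *_: NullFit(), rng)
        assert len(res.intervals) == 0
        assert res.selected == ()

    def test_split_seed_determinism(self, small_xy):
        x, y = small_xy
        selector = lambda xa, ya: lasso_fit(xa, ya, tuning="cv", seed=5)
        a = split_inference(x, y, 0.9, selector, 42)
        b = split_inference(x, y, 0.9, selector, 42)
        assert a.selected == b.selected
        assert np.array_equal(a.intervals.lower, b.intervals.lower)

    def test_selective_coverage_of_submodel_target(self):
        # selection on half A is independent of half B, so half-B t-intervals
        # cover the submodel target at the nominal level
        rng = np.random.default_rng(321)
        n, level = 80, 0.90
        sigma_mat = np.eye(4)
        sigma_mat[0, 1] = sigma_mat[1, 0] = 0.8
        beta = np.array([1.0, 0.0, 0.5, 0.0])
        chol = np.linalg.cholesky(sigma_mat)
        hits = pairs = 0
        for rep in range(1000):
            z = rng.standard_normal((n, 4)) @ chol.T
            x = (z - z.mean(0)) / z.std(0, ddof=1)
            y = x @ beta + rng.standard_normal(n)
            res = split_inference(x, y, level,
                                  lambda xa, ya: lasso_fit(xa, ya, tuning="cv", seed=rep),
                                  rng)
            if len(res.intervals) == 0:
                continue
            target = dict(zip(*[submodel_target(sigma_mat, beta, res.selected).model,
                                submodel_target(sigma_mat, beta, res.selected).values]))
            for k, j in enumerate(res.intervals.indices):
                pairs += 1
                hits += res.intervals.lower[k] <= target[int(j)] <= res.intervals.upper[k]
        coverage = hits / pairs
        assert abs(coverage - level) < 0.03


def _lasso_state(rng, n=25, lam=0.15, beta=(1.0, 0.0)):
    x = standardized_design(rng, n, len(beta))
    y = x @ np.array(beta) + rng.standard_normal(n)
    y -= y.mean()
    coef = fit_lasso(x, y, lam)
    active, signs = extract_active_set(coef)
    return x, y, lam, active, signs


class TestTruncationInterval:
    def test_zero_penalty_unconstrained(self, rng):
        x, y, _, active, signs = _lasso_state(rng, lam=0.0001)
        eta = x[:, 0]
        tr = si_truncation_interval(x, y, 0.0, active, signs, eta)
        assert tr.v_minus == -np.inf and tr.v_plus == np.inf

    def test_observed_contrast_inside(self, rng):
        for _ in range(10):
            x, y, lam, active, signs = _lasso_state(rng)
            if not active:
                continue
            xm = x[:, list(active)]
            eta = (xm @ np.linalg.inv(xm.T @ xm))[:, 0]
            tr = si_truncation_interval(x, y, lam, active, signs, eta)
            assert tr.v_minus <= eta @ y <= tr.v_plus

    def test_inconsistent_selection_rejected(self, rng):
        x, y, lam, active, signs = _lasso_state(rng)
        if not active:
            pytest.skip("no active variable in this draw")
        wrong = -np.asarray(signs)
        with pytest.raises(InconsistentSelectionError):
            si_truncation_interval(x, y, lam, active, wrong, x[:, active[0]])

    def test_grid_refit_oracle_two_variables(self):
        # scan eta'y along its direction and refit the Lasso at each grid
        # point: the active/sign pattern matches the observed one exactly
        # when eta'y lies inside [V-, V+]
        rng = np.random.default_rng(8)
        x = standardized_design(rng, 25, 2)
        y = x @ np.array([0.9, 0.0]) + rng.standard_normal(25)
        y -= y.mean()
        lam = 0.18
        coef = fit_lasso(x, y, lam)
        active, signs = extract_active_set(coef)
        assert active  # needs a nonempty selection to be informative
        xm = x[:, list(active)]
        eta = (xm @ np.linalg.inv(xm.T @ xm))[:, 0]
        tr = si_truncation_interval(x, y, lam, active, signs, eta)
        x_obs = eta @ y
        c = eta / (eta @ eta)
        z = y - c * x_obs
        grid = np.linspace(x_obs - 6.0, x_obs + 6.0, 2001)
        step = grid[1] - grid[0]
        for t in grid:
            refit = fit_lasso(x, z + c * t, lam)
            a2, s2 = extract_active_set(refit, tol=1e-10)
            same = a2 == active and np.array_equal(s2, signs)
            inside = tr.v_minus <= t <= tr.v_plus
            if same != inside:
                # allow disagreement within one grid step of a boundary
                assert min(abs(t - tr.v_minus), abs(t - tr.v_plus)) <= step


class TestSelectiveCI:
    def test_untruncated_equals_plugin_wald(self, rng):
        x, y, lam, active, signs = _lasso_state(rng)
        if not active:
            pytest.skip("no active variable in this draw")
        ivs = si_ci(x, y, 0.0, tuple(range(x.shape[1])), np.sign(fit_lasso(x, y, 0.0)),
                    sigma2=1.3, level=0.90)
        w = wald_ci(x, y, 0.90, variance_mode="plugin", sigma2=1.3)
        assert np.allclose(ivs.lower, w.lower, atol=1e-6)
        assert np.allclose(ivs.upper, w.upper, atol=1e-6)

    def test_pivot_limits_monotone_in_observed_contrast(self):
        # on a fixed truncation interval, both confidence limits are
        # nondecreasing in eta'y
        from postsel.inference import _invert_pivot

        v_minus, v_plus, sd = -1.0, 3.0, 0.7
        lowers, uppers = [], []
        for x_obs in np.linspace(-0.8, 2.8, 40):
            lowers.append(_invert_pivot(0.95, x_obs, sd, v_minus, v_plus))
            uppers.append(_invert_pivot(0.05, x_obs, sd, v_minus, v_plus))
        assert np.all(np.diff(lowers) >= -1e-7)
        assert np.all(np.diff(uppers) >= -1e-7)

    def test_median_unbiased_estimate_inside_finite_intervals(self, rng):
        from postsel.inference import _invert_pivot, _pivot

        for _ in range(10):
            x, y, lam, active, signs = _lasso_state(rng)
            if not active:
                continue
            ivs = si_ci(x, y, lam, active, signs, sigma2=1.0, level=0.9)
            xm = x[:, list(active)]
            contrasts = xm @ np.linalg.inv(xm.T @ xm)
            for k in range(len(ivs)):
                if not np.isfinite(ivs.lower[k]) or not np.isfinite(ivs.upper[k]):
                    continue
                eta = contrasts[:, k]
                tr = si_truncation_interval(x, y, lam, active, signs, eta)
                mu_med = _invert_pivot(0.5, float(eta @ y),
                                       float(np.sqrt(eta @ eta)),
                                       tr.v_minus, tr.v_plus)
                assert ivs.lower[k] - 1e-8 <= mu_med <= ivs.upper[k] + 1e-8

    def test_conditional_coverage_at_fixed_lambda(self):
        # condition on the most frequent pattern; coverage of the X-based
        # submodel target should be nominal with known sigma
        rng = np.random.default_rng(11)
        n, lam, level = 50, 0.25, 0.90
        sigma_mat = np.array([[1.0, 0.3], [0.3, 1.0]])
        beta = np.array([0.8, 0.0])
        chol = np.linalg.cholesky(sigma_mat)
        kept = covered = draws = 0
        while kept < 1000 and draws < 12_000:
            draws += 1
            z = rng.standard_normal((n, 2)) @ chol.T
            x = (z - z.mean(0)) / z.std(0, ddof=1)
            y = x @ beta + rng.standard_normal(n)
            y -= y.mean()
            active, signs = extract_active_set(fit_lasso(x, y, lam))
            if active != (0,) or signs[0] != 1.0:
                continue
            kept += 1
            xm = x[:, [0]]
            target = float(np.linalg.lstsq(xm, x @ beta, rcond=None)[0][0])
            ivs = si_ci(x, y, lam, active, signs, sigma2=1.0, level=level)
            covered += ivs.lower[0] <= target <= ivs.upper[0]
        assert kept == 1000
        assert abs(covered / kept - level) < 0.03


class TestWidthAlarm:
    def test_flags_only_extreme_ratios(self, small_xy):
        from postsel.inference import flag_extreme_widths

        x, y = small_xy
        ref = wald_ci(x, y, 0.9, variance_mode="plugin", sigma2=1.0)
        wide = IntervalSet(
            indices=ref.indices, estimate=ref.estimate,
            lower=ref.lower * 500, upper=ref.upper * 500,
            method="si", level=0.9,
        )
        assert flag_extreme_widths(wide, ref).all()
        assert not flag_extreme_widths(ref, ref).any()


class TestPoSI:
    def test_single_variable_reduces_to_gaussian_quantile(self, rng):
        x = standardized_design(rng, 30, 1)
        k = posi_constant(x, 0.90, n_mc=100_000, seed=1)
        assert abs(k - norm.ppf(0.95)) < 0.02

    def test_orthogonal_two_variable_closed_form(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((40, 2)))
        x = q * np.sqrt(40)
        k = posi_constant(x, 0.90, n_mc=200_000, seed=2)
        k_true = brentq(lambda v: (2 * norm.cdf(v) - 1) ** 2 - 0.90, 1.0, 4.0)
        assert abs(k - k_true) < 0.02

    def test_monotone_in_dimension_for_nested_orthogonal_designs(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((50, 4)))
        x = q * np.sqrt(50)
        ks = [posi_constant(x[:, : p + 1], 0.90, n_mc=50_000, seed=3)
              for p in range(4)]
        assert all(b >= a - 0.01 for a, b in zip(ks, ks[1:]))

    def test_k_dominates_gaussian_quantile(self, rng):
        x = standardized_design(rng, 40, 4)
        k = posi_constant(x, 0.90, n_mc=20_000, seed=4)
        assert k >= norm.ppf(0.95)

    def test_posi_ci_reduces_to_plugin_wald(self, small_xy):
        x, y = small_xy
        k = norm.ppf(0.95)
        a = posi_ci(x, y, k, sigma2=1.0, level=0.9)
        b = wald_ci(x, y, 0.9, variance_mode="plugin", sigma2=1.0)
        assert np.allclose(a.lower, b.lower) and np.allclose(a.upper, b.upper)

    def test_widths_linear_in_k(self, small_xy):
        x, y = small_xy
        a = posi_ci(x, y, 1.0, sigma2=1.0)
        b = posi_ci(x, y, 3.0, sigma2=1.0)
        assert np.allclose(b.width, 3.0 * a.width)

    def test_familywise_error_controlled(self):
        # simultaneous non-coverage over all (M, j) pairs stays below alpha
        rng = np.random.default_rng(9)
        n, p, level = 30, 3, 0.90
        x = standardized_design(rng, n, p)
        k = posi_constant(x, level, n_mc=100_000, seed=10)
        beta = np.array([0.5, 0.0, -0.3])
        mu = x @ beta
        models = [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]
        targets = {m: np.linalg.lstsq(x[:, list(m)], mu, rcond=None)[0] for m in models}
        n_rep, fwer = 1000, 0
        for _ in range(n_rep):
            y = mu + rng.standard_normal(n)
            miss = False
            for m in models:
                ivs = posi_ci(x[:, list(m)], y, k, sigma2=1.0, level=level)
                t = targets[m]
                if np.any((t < ivs.lower) | (t > ivs.upper)):
                    miss = True
                    break
            fwer += miss
        assert fwer / n_rep <= (1 - level) + 0.02
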