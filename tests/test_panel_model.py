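"""First-difference construction, the no-intercept ML mixed model, and the
descriptive/diagnostic statistics around it."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from ebsmr import panel as pm


def _toy_resources(phn0=20.0, phn1=40.0):
    rows = []
    for period, phn in [("2010", phn0), ("2015", phn1)]:
        rows.append({
            "municipality_id": "M0", "prefecture_id": "P0", "period": period,
            "population": 100_000.0, "phn_total": phn, "phn_full_time": phn,
            "phn_part_time": 1.0, "physicians": 50.0, "clinics": 30.0,
            "hospitals": 5.0, "welfare_facilities": 8.0,
        })
    return pd.DataFrame(rows)


def _toy_ebsmr(vals=(100.0, 90.0)):
    return pd.DataFrame([
        {"municipality_id": "M0", "sex": "male", "cause": "all_causes",
         "period": "2010", "ebsmr": vals[0]},
        {"municipality_id": "M0", "sex": "male", "cause": "all_causes",
         "period": "2015", "ebsmr": vals[1]},
    ])


class TestFirstDifference:
    def test_identical_periods_give_zero_differences(self):
        res = _toy_resources(20.0, 20.0)
        rows = pm.build_first_difference(_toy_ebsmr((100.0, 100.0)), res)
        diff_cols = [c for c in rows.columns if c.startswith("d_")]
        assert np.allclose(rows[diff_cols].to_numpy(dtype=float), 0.0)
        assert rows["dy"].iloc[0] == 0.0

    def test_phn_doubling_gives_log_two(self):
        rows = pm.build_first_difference(_toy_ebsmr(), _toy_resources(20.0, 40.0))
        assert rows["d_ln_phn"].iloc[0] == pytest.approx(np.log(2), abs=1e-12)
        assert rows["dy"].iloc[0] == pytest.approx(-10.0)

    def test_row_count_matches_complete_municipalities(self, small_panel, small_ebsmr):
        rows = pm.build_first_difference(small_ebsmr, small_panel["resources"])
        n_muni = small_panel["panel"]["municipality_id"].nunique()
        n_series = (small_ebsmr["sex"].nunique()
                    * small_ebsmr["cause"].nunique())
        assert len(rows) == n_muni * n_series

    def test_zero_phn_raises_by_default_and_offsets_on_request(self):
        res = _toy_resources(0.0, 40.0)
        with pytest.raises(ValueError, match="M0"):
            pm.build_first_difference(_toy_ebsmr(), res)
        rows = pm.build_first_difference(_toy_ebsmr(), res, zero_phn="offset")
        assert np.isfinite(rows["d_ln_phn"]).all()


def _simulate_lmm(rng, n=1600, n_groups=47, beta=(-1.0, 0.5), s_u=2.0, s_e=5.0):
    p = len(beta)
    X = rng.normal(0, 1, (n, p))
    g = np.repeat(np.arange(n_groups), int(np.ceil(n / n_groups)))[:n]
    u = rng.normal(0, s_u, n_groups)
    y = X @ np.asarray(beta) + u[g] + rng.normal(0, s_e, n)
    return y, X, g


def _gls_oracle(y, X, g, s_u, s_e):
    """Closed-form GLS with the true variance components."""
    n = y.size
    V = s_e ** 2 * np.eye(n)
    for lab in np.unique(g):
        idx = np.flatnonzero(g == lab)
        V[np.ix_(idx, idx)] += s_u ** 2
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    se = np.sqrt(np.diag(np.linalg.inv(A)))
    return beta, se


class TestMixedModel:
    def test_zero_group_variance_reduces_to_ols(self, rng):
        y, X, g = _simulate_lmm(rng, n=400, n_groups=8, s_u=0.0, s_e=3.0)
        fit = pm.fit_lmm_ml(y, X, groups=g)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.sigma2_u <= 1e-6 * fit.sigma2_e
        assert np.max(np.abs(fit.beta - ols)) < 1e-6

    def test_matches_gls_with_true_components(self, rng):
        y, X, g = _simulate_lmm(rng)
        fit = pm.fit_lmm_ml(y, X, groups=g)
        beta_gls, se_gls = _gls_oracle(y, X, g, 2.0, 5.0)
        assert np.all(np.abs(fit.beta - beta_gls) < 3 * se_gls)
        assert fit.sigma2_u == pytest.approx(4.0, rel=0.35)
        assert fit.sigma2_e == pytest.approx(25.0, rel=0.2)

    def test_agrees_with_statsmodels_mixedlm(self, rng):
        """Independent cross-check of the ML fit against statsmodels."""
        import statsmodels.api as sm

        y, X, g = _simulate_lmm(rng, n=600, n_groups=12, s_u=1.5, s_e=2.0)
        fit = pm.fit_lmm_ml(y, X, groups=g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert np.max(np.abs(fit.beta - ref.fe_params)) < 1e-4
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert fit.sigma2_e == pytest.approx(ref.scale, rel=1e-3)

    def test_exact_fit_handled(self, rng):
        X = rng.normal(0, 1, (50, 2))
        y = X @ np.array([2.0, -1.0])
        fit = pm.fit_lmm_ml(y, X, groups=np.arange(50) % 5)
        assert np.max(np.abs(fit.beta - [2.0, -1.0])) < 1e-6

    def test_rank_deficient_design_rejected(self, rng):
        X = rng.normal(0, 1, (30, 2))
        X = np.column_stack([X[:, 0], X[:, 0]])
        with pytest.raises(pm.RankDeficiencyError):
            pm.fit_lmm_ml(rng.normal(0, 1, 30), X, groups=np.arange(30) % 3)

    def test_random_effect_never_hurts_loglik(self, rng):
        y, X, g = _simulate_lmm(rng, n=300, n_groups=10, s_u=1.0, s_e=2.0)
        with_re = pm.fit_lmm_ml(y, X, groups=g)
        without = pm.fit_lmm_ml(y, X, groups=None)
        assert with_re.loglik >= without.loglik - 1e-8
        assert with_re.aic == pytest.approx(
            -2 * with_re.loglik + 2 * (X.shape[1] + 2))

    def test_singleton_groups_reduce_to_ols(self, rng):
        y, X, _ = _simulate_lmm(rng, n=120, n_groups=2, s_u=0.0, s_e=1.0)
        fit = pm.fit_lmm_ml(y, X, groups=np.arange(120))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(fit.beta - ols)) < 1e-6


class TestFirstDifferenceFixedEffectsIdentity:
    def test_identity_on_synthetic_two_period_panel(self, rng):
        n = 200
        muni = np.tile(np.arange(n), 2)
        period = np.repeat(["a", "b"], n)
        X = rng.normal(0, 1, (2 * n, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 1, 2 * n)
        rep = pm.first_difference_equals_fixed_effects(y, X, muni, period)
        assert rep.max_abs_diff <= 1e-8

    def test_hand_solved_three_municipality_panel(self):
        # single covariate; dx = (1, 2, 1), dy = (3, 4, 2):
        # FD slope = sum(dx*dy)/sum(dx^2) = 13/6
        muni = np.array(["a", "b", "c", "a", "b", "c"])
        period = np.array([0, 0, 0, 1, 1, 1])
        x = np.array([[0.0], [1.0], [2.0], [1.0], [3.0], [3.0]])
        y = np.array([0.0, 1.0, 0.0, 3.0, 5.0, 2.0])
        rep = pm.first_difference_equals_fixed_effects(y, x, muni, period)
        assert rep.beta_fd[0] == pytest.approx(13 / 6)
        assert rep.max_abs_diff <= 1e-12

    def test_three_periods_unsupported(self, rng):
        with pytest.raises(pm.UnsupportedDesignError):
            pm.first_difference_equals_fixed_effects(
                rng.normal(size=6), rng.normal(size=(6, 1)),
                np.tile([0, 1], 3), np.repeat([0, 1, 2], 2))

    def test_constant_covariate_raises_in_both_estimators(self):
        muni = np.array(["a", "b", "a", "b"])
        period = np.array([0, 0, 1, 1])
        x = np.ones((4, 1))
        with pytest.raises(pm.RankDeficiencyError):
            pm.first_difference_equals_fixed_effects(
                np.array([1.0, 2, 3, 4]), x, muni, period)


class TestSimpleRegression:
    def test_exact_proportionality(self):
        x = np.arange(1.0, 11.0)
        slope, p = pm.simple_regression_no_intercept(2 * x, x)
        assert slope == pytest.approx(2.0)
        assert p < 1e-12

    def test_orthogonal_vectors_give_zero_slope(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        slope, p = pm.simple_regression_no_intercept(y, x)
        assert slope == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_lstsq_oracle(self, rng):
        x = rng.normal(0, 2, 60)
        y = -1.4 * x + rng.normal(0, 1, 60)
        slope, _ = pm.simple_regression_no_intercept(y, x)
        oracle = np.linalg.lstsq(x[:, None], y, rcond=None)[0][0]
        assert slope == pytest.approx(oracle, rel=1e-12)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            pm.simple_regression_no_intercept(np.ones(3), np.zeros(3))


class TestVIF:
    def test_orthogonal_columns_give_unit_vif(self):
        X = np.array([[1, 1], [-1, 1], [1, -1], [-1, -1.0]])
        assert np.allclose(pm.vif(X)["vif"], 1.0)

    def test_correlation_point_six_closed_form(self):
        a = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        b = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        X = np.column_stack([a, 0.6 * a + 0.8 * b])  # corr(a, x2) = 0.6 exactly
        assert np.allclose(pm.vif(X)["vif"], 1 / (1 - 0.36))

    def test_duplicated_column_flags_infinity(self, rng):
        x = rng.normal(0, 1, 30)
        assert np.isinf(pm.vif(np.column_stack([x, x]))["vif"]).all()


class TestBHQValues:
    @pytest.mark.parametrize("pvals, expected", [
        ([0.05], [0.05]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ])
    def test_hand_evaluated_step_up(self, pvals, expected):
        assert np.allclose(pm.bh_qvalues(np.array(pvals)), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.bh_qvalues(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=30))
    def test_step_up_properties(self, pvals):
        p = np.array(pvals)
        q = pm.bh_qvalues(p)
        order = np.argsort(p, kind="stable")
        # monotone along sorted p, never below p, capped at 1, and the
        # step-up formula holds exactly
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1 + 1e-12)
        n = p.size
        brute = np.empty(n)
        for i, j in enumerate(order):
            brute[j] = min(min(p[order[k]] * n / (k + 1)
                               for k in range(i, n)), 1.0)
        assert np.allclose(q, brute)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert np.allclose(pm.bh_qvalues(p)[perm], pm.bh_qvalues(p[perm]))


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert pm.cohens_d(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == 0.0

    def test_unit_effect_forced_by_formula(self):
        r2 = np.sqrt(2)
        a = np.array([10 - r2, 10 + r2])  # mean 10, sd 2
        b = np.array([8 - r2, 8 + r2])    # mean 8, sd 2
        assert pm.cohens_d(a, b) == pytest.approx(1.0)

    def test_unequal_n_matches_pooled_formula(self, rng):
        a, b = rng.normal(1, 2, 11), rng.normal(0, 3, 23)
        pooled = np.sqrt((10 * a.var(ddof=1) + 22 * b.var(ddof=1)) / 32)
        assert pm.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_zero_spread_flagged_as_nan(self):
        assert np.isnan(pm.cohens_d(np.ones(3), np.ones(4)))


class TestStratifiedFits:
    def _rows(self, rng, n=300, effect_above_only=True):
        df = pd.DataFrame({
            "baseline_ebsmr": rng.uniform(70, 130, n),
            "baseline_pop": rng.uniform(1e3, 1e5, n),
            "prefecture_id": rng.integers(0, 8, n),
            "x": rng.normal(0, 1, n),
        })
        beta = np.where(df["baseline_ebsmr"] >= 100, -3.0,
                        0.0 if effect_above_only else -3.0)
        df["dy"] = beta * df["x"] + rng.normal(0, 1, n)
        return df

    def test_threshold_at_minimum_puts_all_rows_in_one_stratum(self, rng):
        rows = self._rows(rng)
        fits = pm.stratified_fits(rows, ("x",), "baseline_pop",
                                  rows["baseline_pop"].min())
        assert set(fits) == {"above"}
        assert fits["above"].n == len(rows)

    def test_strata_partition_the_sample(self, rng):
        rows = self._rows(rng)
        fits = pm.stratified_fits(rows, ("x",), "baseline_pop", 10_000.0)
        assert fits["below"].n + fits["above"].n == len(rows)

    def test_effect_recovered_only_in_the_stratum_carrying_it(self, rng):
        rows = self._rows(rng, effect_above_only=True)
        fits = pm.stratified_fits(rows, ("x",), "baseline_ebsmr", 100.0)
        assert fits["above"].beta[0] == pytest.approx(-3.0, abs=0.5)
        assert fits["above"].p[0] < 0.001
        assert abs(fits["below"].beta[0]) < 0.5
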