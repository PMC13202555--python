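import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from mobindex.regress import (
    PriorConfig,
    RegressionSpec,
    auto_cascade,
    fit_bayes,
    fit_m_estimation,
    fit_mlr,
    spearman_matrix,
    vif_screen,
)


def linear_data(rng, n=30, slope=2.0, intercept=1.0, noise=0.5):
    x = rng.uniform(0, 10, n)
    y = intercept + slope * x + rng.normal(0, noise, n)
    return pd.DataFrame({"y": y, "x": x})


class TestVifScreen:
    def test_orthogonal_predictors_all_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        retained, vifs, excluded = vif_screen(X, 5.0)
        assert retained == ["a", "b"]
        assert excluded == {}
        assert all(v == pytest.approx(1.0, abs=1e-10) for v in vifs.values())

    def test_duplicated_column_removed_with_infinite_vif(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        X = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(size=10)})
        retained, _, excluded = vif_screen(X, 5.0)
        assert len(retained) == 2
        assert len(excluded) == 1
        assert math.isinf(next(iter(excluded.values())))

    def test_vif_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        b = 0.8 * a + rng.normal(0, 0.5, 40)
        c = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        _, vifs, _ = vif_screen(X, threshold=1e9)
        import statsmodels.api as sm

        for col in X.columns:
            others = sm.add_constant(X.drop(columns=col))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert vifs[col] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestMLR:
    def test_exact_linear_data_interpolated(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"y": 3.0 + 2.0 * x, "x": x})
        res = fit_mlr(RegressionSpec("y", ["x"]), df)
        assert res.coef("intercept") == pytest.approx(3.0, abs=1e-10)
        assert res.coef("x") == pytest.approx(2.0, abs=1e-10)
        assert res.diagnostics["sigma"] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_recovers_mean(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
        res = fit_mlr(RegressionSpec("y", []), df)
        assert res.coef("intercept") == pytest.approx(2.5)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        n = 25
        X = rng.normal(size=(n, 3))
        beta = np.array([0.5, -1.2, 2.0])
        y = 0.7 + X @ beta + rng.normal(0, 0.3, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        res = fit_mlr(RegressionSpec("y", ["a", "b", "c"]), df)
        Z = np.column_stack([np.ones(n), X])
        theta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        got = res.coefficients["estimate"].to_numpy()
        assert np.allclose(got, theta, atol=1e-10)

    def test_interval_contains_estimate(self):
        res = fit_mlr(RegressionSpec("y", ["x"]), linear_data(np.random.default_rng(3)))
        lo, hi = res.interval("x")
        assert lo <= res.coef("x") <= hi

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=12)
        df = pd.DataFrame({"y": rng.normal(size=12), "a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank"):
            fit_mlr(RegressionSpec("y", ["a", "b"]), df)


class TestMEstimation:
    def test_clean_data_agrees_with_ols(self):
        df = linear_data(np.random.default_rng(5), n=60)
        huber = fit_m_estimation(RegressionSpec("y", ["x"]), df)
        ols = fit_mlr(RegressionSpec("y", ["x"]), df)
        assert huber.coef("x") == pytest.approx(ols.coef("x"), abs=1e-2)

    def test_outlier_pulls_ols_more_than_huber(self):
        rng = np.random.default_rng(6)
        df = linear_data(rng, n=20, slope=2.0, noise=0.3)
        df.loc[df.index[-1], "y"] += 40.0  # one gross y-outlier
        huber = fit_m_estimation(RegressionSpec("y", ["x"]), df)
        ols = fit_mlr(RegressionSpec("y", ["x"]), df)
        assert abs(huber.coef("x") - 2.0) < abs(ols.coef("x") - 2.0)

    def test_converged_weights_reproduce_fit_via_wls(self):
        rng = np.random.default_rng(7)
        df = linear_data(rng, n=30)
        df.loc[df.index[0], "y"] += 15.0
        res = fit_m_estimation(RegressionSpec("y", ["x"]), df)
        assert res.diagnostics["converged"]
        import statsmodels.api as sm

        Z = sm.add_constant(df[["x"]].to_numpy())
        wls = sm.WLS(df["y"].to_numpy(), Z, weights=res.extras["weights"]).fit()
        assert np.allclose(wls.params, res.coefficients["estimate"], atol=1e-6)


class TestBayes:
    def test_likelihood_dominates_at_large_n(self):
        rng = np.random.default_rng(8)
        df = linear_data(rng, n=2000, slope=1.5, noise=0.4)
        spec = RegressionSpec("y", ["x"], chains=2, draws=500, warmup=200, seed=1)
        bayes = fit_bayes(spec, df)
        ols = fit_mlr(spec, df)
        post_sd = (bayes.interval("x")[1] - bayes.interval("x")[0]) / 3.92
        assert abs(bayes.coef("x") - ols.coef("x")) < 2 * post_sd

    def test_fixed_sigma_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(9)
        n = 12
        x = rng.normal(0, 1, n)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x})
        spec = RegressionSpec("y", ["x"], chains=2, draws=5000, warmup=500, seed=2)
        res = fit_bayes(spec, df, fixed_sigma=0.7)
        # conjugate-normal oracle on the standardized scale
        ys = (y - y.mean()) / y.std()
        xs = (x - x.mean()) / x.std()
        Z = np.column_stack([np.ones(n), xs])
        P = np.diag([1 / 1.0**2, 1 / 0.5**2])
        prec = Z.T @ Z / 0.7**2 + P
        mean = np.linalg.solve(prec, Z.T @ ys / 0.7**2)
        expected = mean[1] * y.std() / x.std()
        mc_sd = math.sqrt(np.linalg.inv(prec)[1, 1]) * y.std() / x.std()
        assert res.coef("x") == pytest.approx(expected, abs=4 * mc_sd / math.sqrt(10000))

    def test_identical_seed_reproduces_draws(self):
        df = linear_data(np.random.default_rng(10), n=40)
        spec = RegressionSpec("y", ["x"], chains=2, draws=200, warmup=100, seed=3)
        r1 = fit_bayes(spec, df)
        r2 = fit_bayes(spec, df)
        assert np.array_equal(r1.extras["posterior"]["beta_x"], r2.extras["posterior"]["beta_x"])
        pd.testing.assert_frame_equal(r1.coefficients, r2.coefficients)

    def test_diagnostics_present_and_sane(self):
        df = linear_data(np.random.default_rng(11), n=50)
        spec = RegressionSpec("y", ["x"], chains=4, draws=500, warmup=300, seed=4)
        res = fit_bayes(spec, df)
        d = res.diagnostics
        assert set(d["rhat"]) == {"intercept", "sigma", "beta_x"}
        assert d["max_rhat"] < 1.01
        assert d["min_bulk_ess"] > 400
        assert 0.0 <= d["ppc_p_mean"] <= 1.0
        assert not d["convergence_warning"]

    def test_single_chain_rejected(self):
        df = linear_data(np.random.default_rng(12))
        with pytest.raises(ValueError, match="chains"):
            fit_bayes(RegressionSpec("y", ["x"], chains=1), df)


class TestAutoCascade:
    def test_gaussian_fixture_keeps_mlr(self):
        df = linear_data(np.random.default_rng(13), n=40, noise=1.0)
        res = auto_cascade(RegressionSpec("y", ["x"]), df)
        assert res.family_used == "mlr"

    def test_heavy_tailed_fixture_switches_to_m_estimation(self):
        rng = np.random.default_rng(14)
        df = linear_data(rng, n=24, noise=0.2)
        df.loc[df.index[:3], "y"] += np.array([25.0, -30.0, 28.0])
        mlr = fit_mlr(RegressionSpec("y", ["x"]), df)
        assert mlr.diagnostics["shapiro_p"] < 0.05  # constructed violation
        res = auto_cascade(RegressionSpec("y", ["x"]), df)
        assert res.family_used == "m_estimation"
        assert any("m_estimation" in s for s in res.extras["branch_trail"])

    def test_too_many_predictors_is_an_error(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(5, 5)), columns=list("abcde"))
        df["y"] = rng.normal(size=5)
        with pytest.raises(ValueError, match="observations"):
            auto_cascade(RegressionSpec("y", ["a", "b", "c", "d"]), df)

    def test_vif_exclusions_reported(self):
        rng = np.random.default_rng(16)
        a = rng.normal(size=30)
        df = pd.DataFrame({"a": a, "dup": a + rng.normal(0, 1e-8, 30),
                           "b": rng.normal(size=30)})
        df["y"] = 1.0 + df["a"] + df["b"] + rng.normal(0, 0.5, 30)
        res = auto_cascade(RegressionSpec("y", ["a", "dup", "b"]), df)
        assert len(res.excluded_predictors) == 1


class TestSpearman:
    def test_monotone_pair_is_one(self):
        X = pd.DataFrame({"x": [1, 2, 3, 4, 5.0]})
        Y = pd.DataFrame({"y": [2, 4, 9, 16, 30.0]})
        out = spearman_matrix(X, Y)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_antitone_pair_is_minus_one(self):
        X = pd.DataFrame({"x": [1, 2, 3, 4, 5.0]})
        Y = pd.DataFrame({"y": [-1, -2, -3, -4, -5.0]})
        out = spearman_matrix(X, Y)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_exact_p_matches_scipy_permutation_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=8)
        y = 0.6 * x + rng.normal(0, 1, 8)
        out = spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        from scipy import stats

        def statistic(yp):
            return stats.spearmanr(x, yp).statistic

        ref = stats.permutation_test(
            (y,), statistic, permutation_type="pairings",
            n_resamples=math.factorial(8), alternative="two-sided",
        )
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_column_reported_missing(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        Y = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
        out = spearman_matrix(X, Y)
        assert math.isnan(out.loc[0, "rho"]) and math.isnan(out.loc[0, "p"])

    def test_bh_adjustment_bounds(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        Y = pd.DataFrame(rng.normal(size=(12, 2)), columns=["u", "v"])
        out = spearman_matrix(X, Y, adjust="BH")
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert (out["q"] <= 1.0 + 1e-12).all()
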