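import numpy as np
import pandas as pd
import pytest

import ifnprog as ip
from ifnprog.prediction import (
    _newton_logistic,
    _standardise,
    binomial_deviance,
    default_lambda_path,
    lambda_max,
    logistic_fit,
)


def logistic_data(n=120, p=6, beta=None, intercept=-1.5, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    prob = 1 / (1 + np.exp(-(intercept + x @ beta)))
    return (rng.random(n) < prob).astype(float), x


def small_cohort_df(n=60, missing=0, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = 0.6 * x1 + rng.normal(0, 0.8, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + x1)))).astype(int)
    df = pd.DataFrame({"ifn_score_a": x1, "ifn_score_b": x2, "outcome": y})
    if missing:
        idx = rng.choice(n, missing, replace=False)
        df.loc[df.index[idx], "ifn_score_b"] = np.nan
    return df


class TestMice:
    def test_complete_data_returns_identical_copies(self):
        table = ip.CohortTable(small_cohort_df())
        imp = ip.mice_impute(table, m=4, cycles=2, seed=1)
        assert imp.m == 4
        for df in imp.completed:
            pd.testing.assert_frame_equal(df, table.data)

    def test_deterministic_for_fixed_seed(self):
        table = ip.CohortTable(small_cohort_df(missing=8))
        a = ip.mice_impute(table, m=3, cycles=3, seed=9)
        b = ip.mice_impute(table, m=3, cycles=3, seed=9)
        for da, db in zip(a.completed, b.completed):
            pd.testing.assert_frame_equal(da, db)

    def test_observed_cells_untouched_and_complete(self):
        df = small_cohort_df(missing=8)
        table = ip.CohortTable(df)
        imp = ip.mice_impute(table, m=3, cycles=3, seed=2)
        observed = df["ifn_score_b"].notna()
        for comp in imp.completed:
            assert not comp.isna().any().any()
            np.testing.assert_array_equal(
                comp.loc[observed, "ifn_score_b"], df.loc[observed, "ifn_score_b"]
            )

    def test_mcar_imputation_recovers_deleted_mean(self):
        rng = np.random.default_rng(31)
        n = 300
        x = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], n)
        y = (rng.random(n) < 0.3).astype(int)
        df = pd.DataFrame(
            {"ifn_score_a": x[:, 0], "ifn_score_b": x[:, 1], "outcome": y}
        )
        drop = rng.choice(n, 30, replace=False)
        truth = df.loc[df.index[drop], "ifn_score_b"].copy()
        df.loc[df.index[drop], "ifn_score_b"] = np.nan
        imp = ip.mice_impute(ip.CohortTable(df), m=5, cycles=5, seed=3)
        imputed_means = [
            comp.loc[truth.index, "ifn_score_b"].mean() for comp in imp.completed
        ]
        assert np.mean(imputed_means) == pytest.approx(truth.mean(), abs=0.2)

    def test_fully_missing_variable_rejected(self):
        df = small_cohort_df()
        df["ifn_score_b"] = np.nan
        with pytest.raises(ValueError, match="no observed values"):
            ip.mice_impute(ip.CohortTable(df), m=2, cycles=2, seed=0)


class TestLasso:
    def test_all_slopes_zero_at_lambda_max(self):
        y, x = logistic_data(beta=[1.0, 0, 0.5, 0, 0, 0], seed=4)
        fit = ip.lasso_logistic(y, x)
        assert np.all(fit.coef_std[0] == 0.0)
        # KKT: just below lambda_max at least one slope activates
        xs, _, _ = _standardise(x)
        lmax = lambda_max(y, xs)
        fit2 = ip.lasso_logistic(y, x, lambda_path=np.array([lmax * 0.98]))
        assert np.any(fit2.coef_std[0] != 0.0)

    def test_unpenalised_limit_matches_newton_mle(self):
        y, x = logistic_data(n=50, p=3, beta=[0.8, -0.5, 0.0], seed=7)
        xs, _, _ = _standardise(x)
        path = np.append(default_lambda_path(y, xs, n_lambda=40), 0.0)
        fit = ip.lasso_logistic(y, x, lambda_path=path)
        beta, _ = _newton_logistic(y, np.column_stack([np.ones(50), x]))
        np.testing.assert_allclose(fit.coef[-1], beta[1:], atol=1e-5)
        assert fit.intercept[-1] == pytest.approx(beta[0], abs=1e-5)

    def test_kkt_conditions_along_path(self):
        y, x = logistic_data(n=150, p=5, beta=[1.2, 0, 0, -0.7, 0], seed=5)
        fit = ip.lasso_logistic(y, x)
        xs, _, _ = _standardise(x)
        n = y.size
        for li in (10, 40, 70):
            lam = fit.lambda_path[li]
            beta = fit.coef_std[li]
            eta = fit.intercept[li] + x @ fit.coef[li]
            prob = 1 / (1 + np.exp(-eta))
            grad = xs.T @ (y - prob) / n
            active = beta != 0
            assert np.all(np.abs(grad[~active]) <= lam + 1e-6)
            np.testing.assert_allclose(grad[active], lam * np.sign(beta[active]), atol=1e-6)

    def test_matches_sklearn_l1_solution(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        y, x = logistic_data(n=200, p=4, beta=[1.0, -0.8, 0, 0], seed=9)
        xs, mean, sd = _standardise(x)
        lam = 0.02
        fit = ip.lasso_logistic(y, x, lambda_path=np.array([lam]))
        clf = sklearn.LogisticRegression(
            penalty="l1", C=1.0 / (len(y) * lam), solver="saga", tol=1e-10,
            max_iter=50000,
        ).fit(xs, y)
        np.testing.assert_allclose(fit.coef_std[0], clf.coef_[0], atol=2e-4)

    def test_sparsity_nonincreasing_in_lambda(self):
        y, x = logistic_data(n=150, p=6, beta=[1.5, 0.8, 0, 0, 0, 0], seed=2)
        fit = ip.lasso_logistic(y, x)
        nnz = (fit.coef_std != 0).sum(axis=1)
        # path is decreasing in lambda, so active set grows along it
        assert np.all(np.diff(nnz) >= -1e-9)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="events"):
            ip.lasso_logistic(np.ones(10), np.random.default_rng(0).normal(size=(10, 2)))


class TestLambdaSelection:
    def test_pure_noise_prefers_null_model(self):
        y, x = logistic_data(n=80, p=5, beta=None, seed=21)  # no signal
        fit = ip.select_lambda_loocv(y, x, lambda_path=None)
        assert fit.lambda_1se == pytest.approx(fit.lambda_path[0])
        assert fit.lambda_1se >= fit.lambda_min

    def test_null_deviance_at_infinite_penalty(self):
        y, x = logistic_data(n=60, p=3, beta=[1.0, 0, 0], seed=13)
        pbar = y.mean()
        null_dev = float(np.mean(binomial_deviance(y, np.full(y.size, pbar))))
        fit = ip.lasso_logistic(y, x, lambda_path=np.array([10.0]))
        eta = fit.intercept[0] + x @ fit.coef[0]
        dev = float(np.mean(binomial_deviance(y, 1 / (1 + np.exp(-eta)))))
        assert dev == pytest.approx(null_dev, rel=1e-6)

    def test_one_se_rule_keeps_true_predictor(self):
        # one real effect (OR ~ 3.8 per SD) among noise; the 1-SE model should
        # keep it and drop most noise terms across seeds
        hits, clean = 0, 0
        reps = 5
        for seed in range(reps):
            y, x = logistic_data(
                n=200, p=6, beta=[np.log(3.8), 0, 0, 0, 0, 0], intercept=-1.2,
                seed=100 + seed,
            )
            xs, _, _ = _standardise(x)
            path = default_lambda_path(y, xs, n_lambda=40)
            fit = ip.select_lambda_loocv(y, x, lambda_path=path)
            beta, _ = fit.coef_at(fit.lambda_1se)
            if beta[0] != 0:
                hits += 1
            if (beta[1:] == 0).sum() >= 3:
                clean += 1
        assert hits >= reps - 1
        assert clean >= reps - 1


class TestRubinPooling:
    def test_hand_computed_example(self):
        pooled = ip.pool_rubin([[0.0], [2.0]], [[1.0], [1.0]])
        assert pooled.estimate[0] == pytest.approx(1.0)
        assert pooled.between_var[0] == pytest.approx(2.0)
        assert pooled.total_var[0] == pytest.approx(1.0 + 1.5 * 2.0)

    def test_identical_estimates_have_no_between_variance(self):
        pooled = ip.pool_rubin([[0.7, -0.2]] * 3, [[0.04, 0.09]] * 3)
        np.testing.assert_allclose(pooled.between_var, 0.0, atol=1e-15)
        np.testing.assert_allclose(pooled.total_var, pooled.within_var, atol=1e-15)
        assert np.all(np.isinf(pooled.df))

    def test_pooled_interval_at_least_as_wide_as_within(self):
        rng = np.random.default_rng(3)
        est = rng.normal(1.0, 0.4, size=(8, 2))
        var = np.full((8, 2), 0.05)
        pooled = ip.pool_rubin(est, var, df_complete=50)
        assert np.all(pooled.total_var >= pooled.within_var)
        ci = pooled.conf_int()
        within_half = 1.96 * np.sqrt(var[0])
        assert np.all(
            (np.log(ci[:, 1]) - np.log(ci[:, 0])) / 2 >= within_half - 1e-12
        )

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ip.pool_rubin([[1.0, 2.0]], [[0.1]])
        with pytest.raises(ValueError, match="m >= 2"):
            ip.pool_rubin([[1.0]], [[0.1]])


class TestScreenAndModels:
    def test_outcome_copy_is_kept_and_alpha_one_keeps_all(self):
        rng = np.random.default_rng(8)
        n = 80
        y = (rng.random(n) < 0.3).astype(int)
        df = pd.DataFrame(
            {
                "ifn_score_a": rng.normal(size=n),
                "ifn_score_b": y + rng.normal(0, 0.1, n),
                "outcome": y,
            }
        )
        imp = ip.mice_impute(ip.CohortTable(df), m=2, cycles=1, seed=0)
        with pytest.warns(UserWarning, match="separation|ridge"):
            kept, table = ip.univariable_screen(imp, ["ifn_score_a", "ifn_score_b"])
        assert "ifn_score_b" in kept
        kept_all, _ = ip.univariable_screen(
            imp, ["ifn_score_a", "ifn_score_b"], alpha=1.0
        )
        assert kept_all == ["ifn_score_a", "ifn_score_b"]

    def test_noise_predictor_usually_excluded(self):
        excluded = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(500 + seed)
            n = 500
            y = (rng.random(n) < 0.2).astype(int)
            df = pd.DataFrame(
                {"ifn_score_a": rng.normal(size=n), "outcome": y}
            )
            imp = ip.mice_impute(ip.CohortTable(df), m=2, cycles=1, seed=seed)
            kept, _ = ip.univariable_screen(imp, ["ifn_score_a"], alpha=0.10)
            if not kept:
                excluded += 1
        assert excluded >= 0.85 * reps - 1  # >=8/10 at the 10% level

    def test_multivariable_pooled_recovers_effect(self):
        df = small_cohort_df(n=400, missing=30, seed=6)
        imp = ip.mice_impute(ip.CohortTable(df), m=5, cycles=3, seed=1)
        fit = ip.multivariable_pooled(imp, ["ifn_score_a", "ifn_score_b"])
        frame = fit.to_frame()
        # true model: log-OR 1 on score_a, 0 on score_b
        assert frame.loc["ifn_score_a", "or"] == pytest.approx(np.e, rel=0.5)
        assert frame.loc["ifn_score_a", "p"] < 0.01

    def test_separation_fallback_is_finite(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = y[:, None] * 2 - 1  # perfectly separating predictor
        with pytest.warns(UserWarning, match="separation"):
            beta, var = logistic_fit(y, x)
        assert np.all(np.isfinite(beta)) and np.all(np.isfinite(var))
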