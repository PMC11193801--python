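"""Relaxed lasso: standardization, coordinate descent, LOOCV, OLS refit."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from wmlearn.model_selection import (
    LassoPath,
    _cd_path_python,
    auto_lambda_grid,
    lasso_objective,
    lasso_path,
    loocv_errors,
    loocv_select,
    marginal_regressions,
    relaxed_refit,
    select_model,
    standardize,
)
from wmlearn.synthetic import CohortSimConfig, simulate_cohort


def _random_design(n=30, p=5, seed=0, signal=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    if signal:
        for j, b in signal.items():
            beta[j] = b
    y = X @ beta + rng.normal(size=n)
    table = pd.DataFrame(X, columns=[f"t{j}" for j in range(p)],
                         index=[f"s{i}" for i in range(n)])
    return table, pd.Series(y, index=table.index)


class TestStandardize:
    def test_columns_centered_and_scaled(self):
        table, y = _random_design(seed=1)
        design = standardize(table, y)
        np.testing.assert_allclose(design.matrix.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(design.matrix.std(axis=0, ddof=1), 1, atol=1e-10)
        assert design.outcome.mean() == pytest.approx(0, abs=1e-10)

    def test_zero_variance_column_named(self):
        table, y = _random_design()
        table["t2"] = 1.0
        with pytest.raises(ValueError, match="t2"):
            standardize(table, y)

    def test_fitted_values_match_raw_space_model(self):
        # OLS fits are invariant to the affine standardization
        table, y = _random_design(n=40, seed=2)
        design = standardize(table, y)
        beta_std = np.linalg.lstsq(design.matrix, design.outcome, rcond=None)[0]
        fitted_std = design.outcome_center + design.matrix @ beta_std
        Xr = np.column_stack([np.ones(len(table)), table.to_numpy()])
        beta_raw = np.linalg.lstsq(Xr, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fitted_std, Xr @ beta_raw, atol=1e-10)

    def test_variance_mode(self):
        table, y = _random_design(seed=3)
        design = standardize(table, y, mode="variance")
        sds = table.std(ddof=1).to_numpy()
        np.testing.assert_allclose(
            design.matrix.std(axis=0, ddof=1), 1.0 / sds, atol=1e-10
        )


class TestLassoPath:
    def test_lambda_max_gives_zero_solution(self):
        table, y = _random_design(n=50, seed=4, signal={0: 1.0})
        design = standardize(table, y)
        path = lasso_path(design)
        assert path.support_sizes[0] == 0
        np.testing.assert_array_equal(path.coefficients[0], 0)

    def test_lambda_to_zero_matches_ols(self):
        table, y = _random_design(n=50, p=4, seed=5, signal={1: 0.8})
        design = standardize(table, y)
        grid = auto_lambda_grid(design.matrix, design.outcome, n_grid=60, decades=8)
        path = lasso_path(design, lambda_grid=grid)
        ols = np.linalg.lstsq(design.matrix, design.outcome, rcond=None)[0]
        np.testing.assert_allclose(path.coefficients[-1], ols, atol=1e-6)

    def test_kkt_conditions_along_path(self):
        table, y = _random_design(n=60, p=6, seed=6, signal={0: 0.7, 3: -0.5})
        design = standardize(table, y)
        path = lasso_path(design)
        X, yc = design.matrix, design.outcome
        n = X.shape[0]
        for k in range(0, len(path.lambda_grid), 10):
            lam = path.lambda_grid[k]
            beta = path.coefficients[k]
            grad = X.T @ (yc - X @ beta) / n
            active = beta != 0
            np.testing.assert_allclose(
                grad[active], lam * np.sign(beta[active]), atol=1e-6
            )
            assert np.all(np.abs(grad[~active]) <= lam + 1e-6)

    def test_numba_matches_python_reference(self):
        table, y = _random_design(n=40, p=8, seed=7, signal={2: 0.6})
        design = standardize(table, y)
        path = lasso_path(design)
        ref = _cd_path_python(design.matrix, design.outcome, path.lambda_grid)
        np.testing.assert_allclose(path.coefficients, ref, atol=1e-12)

    def test_objective_monotone_over_sweeps(self):
        table, y = _random_design(n=40, p=8, seed=8, signal={2: 0.6})
        design = standardize(table, y)
        grid = auto_lambda_grid(design.matrix, design.outcome)[40:41]
        _, objectives = _cd_path_python(
            design.matrix, design.outcome, grid, record_objective=True
        )
        diffs = np.diff(objectives)
        assert np.all(diffs <= 1e-12)

    def test_matches_sklearn_lasso(self):
        # independent implementation cross-check at several penalties
        table, y = _random_design(n=80, p=10, seed=9, signal={0: 1.0, 4: -0.7})
        design = standardize(table, y)
        grid = auto_lambda_grid(design.matrix, design.outcome, n_grid=20, decades=3)
        path = lasso_path(design, lambda_grid=grid)
        for k in (0, 5, 10, 19):
            sk = Lasso(alpha=grid[k], fit_intercept=False, tol=1e-12, max_iter=100000)
            sk.fit(design.matrix, design.outcome)
            np.testing.assert_allclose(path.coefficients[k], sk.coef_, atol=1e-6)

    def test_nonfinite_rejected(self):
        table, y = _random_design()
        y.iloc[0] = np.nan
        with pytest.raises(ValueError):
            standardize(table, y)


class TestLoocv:
    def test_matches_naive_double_loop(self):
        table, y = _random_design(n=20, p=5, seed=10, signal={1: 0.8})
        design = standardize(table, y)
        grid = auto_lambda_grid(design.matrix, design.outcome, n_grid=25)
        cv = loocv_errors(design, grid)
        # independently coded literal double loop over (left-out row, lambda)
        naive = np.zeros((len(table), len(grid)))
        for i in range(len(table)):
            train = table.drop(table.index[i])
            ytrain = y.drop(y.index[i])
            centers = train.mean()
            scales = train.std(ddof=1)
            Xs = ((train - centers) / scales).to_numpy()
            yc = (ytrain - ytrain.mean()).to_numpy()
            sub = standardize(train, ytrain)
            fold_path = lasso_path(sub, lambda_grid=grid)
            x_hold = ((table.iloc[i] - centers) / scales).to_numpy()
            for k in range(len(grid)):
                pred = ytrain.mean() + fold_path.coefficients[k] @ x_hold
                naive[i, k] = (y.iloc[i] - pred) ** 2
        np.testing.assert_allclose(cv, naive.mean(axis=0), atol=1e-10)

    def test_ties_broken_toward_larger_lambda(self):
        table, y = _random_design(n=20, p=4, seed=11)
        design = standardize(table, y)
        lam_max = auto_lambda_grid(design.matrix, design.outcome, 2, 1)[0]
        grid = np.array([4 * lam_max, 3 * lam_max, 2 * lam_max])
        path = lasso_path(design, lambda_grid=grid)
        chosen = loocv_select(design, path)
        # every penalty yields the all-zero model -> identical CV errors -> tie
        assert np.ptp(path.cv_errors) == 0
        assert chosen == grid[0]

    def test_deterministic(self):
        table, y = _random_design(n=25, p=6, seed=12, signal={0: 0.9})
        a = select_model(table, y)
        b = select_model(table, y)
        assert a.selected_tracts == b.selected_tracts
        assert a.chosen_lambda == b.chosen_lambda


class TestRelaxedRefit:
    def test_exact_linear_outcome(self):
        table, _ = _random_design(n=30, p=5, seed=13)
        y = pd.Series(2.0 * table["t1"] - table["t3"], index=table.index)
        design = standardize(table, y)
        res = relaxed_refit(design, ["t1", "t3"], "drawing")
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_empty_support(self):
        table, y = _random_design()
        design = standardize(table, y)
        res = relaxed_refit(design, [])
        assert res.r2 == 0.0 and res.beta == [] and res.selected_tracts == []

    def test_matches_linear_algebra_oracle(self):
        # 6-row fixture, hand-computed (X'X)^-1 X'y and sigma^2 (X'X)^-1
        table, y = _random_design(n=6, p=3, seed=14, signal={0: 1.0})
        design = standardize(table, y)
        res = relaxed_refit(design, ["t0", "t2"])
        idx = [0, 2]
        Xs = design.matrix[:, idx]
        beta = np.linalg.inv(Xs.T @ Xs) @ Xs.T @ design.outcome
        resid = design.outcome - Xs @ beta
        sigma2 = (resid @ resid) / (6 - 2 - 1)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xs.T @ Xs)))
        np.testing.assert_allclose(res.beta, beta, atol=1e-10)
        np.testing.assert_allclose(res.se, se, atol=1e-10)

    def test_debiasing_never_fits_worse(self):
        # OLS refit on the lasso support has in-sample R^2 >= the shrunken fit
        table, y = _random_design(n=50, p=8, seed=15, signal={1: 0.8, 5: 0.5})
        design = standardize(table, y)
        path = lasso_path(design)
        sst = float(design.outcome @ design.outcome)
        for k in range(10, 100, 20):
            beta = path.coefficients[k]
            support = [design.column_names[j] for j in np.nonzero(beta)[0]]
            if not support or len(support) >= len(table) - 1:
                continue
            shrunk_r2 = 1 - float(
                np.sum((design.outcome - design.matrix @ beta) ** 2)
            ) / sst
            assert relaxed_refit(design, support).r2 >= shrunk_r2 - 1e-12


class TestSelectModel:
    def test_noiseless_single_tract(self):
        table, _ = _random_design(n=30, p=5, seed=16)
        y = pd.Series(0.5 * table["t2"], index=table.index)
        res = select_model(table, y, "drawing")
        assert res.selected_tracts == ["t2"]
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_true_support_recovered_strong_signal(self):
        cfg = CohortSimConfig(
            n_participants=200,
            seed=17,
            target_r2_drawing=0.5,
            true_coefficients_drawing={"L_pArc": 0.5, "L_SLF3": 0.5},
        )
        features, latents, truth = simulate_cohort(cfg)
        res = select_model(features, latents["draw_slope"], "drawing")
        assert set(truth.true_support_drawing) <= set(res.selected_tracts)


class TestMarginalRegressions:
    def test_t_matches_closed_form(self):
        table, y = _random_design(n=10, p=2, seed=18, signal={0: 1.0})
        out = marginal_regressions(table, pd.DataFrame({"drawing": y}))
        from scipy import stats

        for _, row in out.iterrows():
            x = table[row["tract"]].to_numpy()
            b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            resid = y - y.mean() - b * (x - x.mean())
            se = np.sqrt((resid @ resid) / 8 / ((x - x.mean()) ** 2).sum())
            assert row["t"] == pytest.approx(b / se, abs=1e-10)
            assert row["p"] == pytest.approx(2 * stats.t.sf(abs(b / se), 8), abs=1e-10)

    def test_null_false_positive_rate(self):
        hits = total = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                rng.normal(size=(48, 22)), columns=[f"t{j}" for j in range(22)]
            )
            outcomes = pd.DataFrame(
                {"drawing": rng.normal(size=48), "recognition": rng.normal(size=48)},
                index=table.index,
            )
            out = marginal_regressions(table, outcomes)
            hits += int(out["significant"].sum())
            total += len(out)
        assert 0.03 <= hits / total <= 0.07

    def test_perfectly_predictive_tract(self):
        table, _ = _random_design(n=20, p=3, seed=19)
        outcomes = pd.DataFrame({"drawing": table["t0"]}, index=table.index)
        out = marginal_regressions(table, outcomes).set_index("tract")
        assert out.loc["t0", "p"] < 1e-30
        assert out.loc["t0", "beta"] == pytest.approx(1.0, abs=1e-10)
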