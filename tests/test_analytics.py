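"""Analytics pipeline: screening, VIF, SVR, importance, Shapley."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from upho.analytics import (
    AnalyticsConfig,
    PipelineError,
    SdohSvr,
    apply_vif_threshold,
    compute_vif,
    cv_folds,
    evaluate,
    fit_svr_linear,
    grid_search_cv,
    importance,
    run_analytics,
    shapley_linear,
    spearman,
    split_standardize,
    svr_objective,
)
from upho.tracts import GeneratorConfig, generate_tracts, recovery_weights

# Published Spearman/VIF screen of the seven retained features.
TABLE2_VIFS = {
    "low_access_supermarket": 1.70,
    "pct_black": 2.80,
    "poverty": 3.66,
    "unemployment": 3.02,
    "no_hs_diploma": 3.55,
    "lack_physical_activity": 8.82,
    "crime_rate": 1.68,
}


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self, rng):
        x = rng.uniform(0, 10, 30)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self, rng):
        x = rng.uniform(0, 1, 25)
        rho, _ = spearman(x, 10.0 - x)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))

    def test_p_value_close_to_exact_permutation_p(self):
        """The t-approximation p-value lands within 10% of the exact
        permutation p over all 8! orderings of a fixed 8-point pair."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([6.0, 7.0, 4.0, 5.0, 2.0, 8.0, 1.0, 3.0])
        rho_obs, p_approx = spearman(x, y)
        rx = x.argsort().argsort().astype(float)
        ry = y.argsort().argsort().astype(float)
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        rhos = (perms_c @ rx_c) / np.sqrt(
            (perms_c**2).sum(axis=1) * (rx_c**2).sum()
        )
        p_exact = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert abs(p_approx - p_exact) <= 0.1 * p_exact


class TestVif:
    def test_orthogonal_centered_features_have_unit_vif(self):
        from scipy.linalg import hadamard

        base = hadamard(32)[:, 1:4].astype(float)  # orthogonal, centered
        table = pd.DataFrame(base, columns=["a", "b", "c"])
        res = compute_vif(table, ["a", "b", "c"])
        assert all(v == pytest.approx(1.0) for v in res.vif.values())

    def test_duplicated_column_reported_infinite_and_removed(self, rng):
        x = rng.standard_normal(50)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)})
        res = compute_vif(table, ["a", "b", "c"], threshold=10)
        assert math.isinf(res.vif["a"]) and math.isinf(res.vif["b"])
        assert res.retained == ["c"]

    def test_matches_normal_equations_oracle(self, rng):
        """Direct normal-equations OLS oracle on a random 9-feature table
        agrees to 1e-8."""
        n, p = 200, 9
        x = rng.standard_normal((n, p)) @ rng.uniform(0.5, 1.5, (p, p))
        cols = [f"f{j}" for j in range(p)]
        table = pd.DataFrame(x, columns=cols)
        res = compute_vif(table, cols)
        for j, f in enumerate(cols):
            others = np.column_stack(
                [np.ones(n), np.delete(x, j, axis=1)]
            )
            beta = np.linalg.solve(others.T @ others, others.T @ x[:, j])
            resid = x[:, j] - others @ beta
            r2 = 1 - resid @ resid / np.sum(
                (x[:, j] - x[:, j].mean()) ** 2
            )
            assert res.vif[f] == pytest.approx(1 / (1 - r2), abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )

        x = rng.standard_normal((80, 4)) @ rng.uniform(0.5, 2, (4, 4))
        cols = list("abcd")
        table = pd.DataFrame(x, columns=cols)
        res = compute_vif(table, cols)
        design = sm.add_constant(x)
        for j, f in enumerate(cols):
            ref = variance_inflation_factor(design, j + 1)
            assert res.vif[f] == pytest.approx(ref, rel=1e-8)


class TestVifThreshold:
    def test_published_screen_retains_all_seven(self):
        retained = apply_vif_threshold(TABLE2_VIFS, 10.0)
        assert retained == list(TABLE2_VIFS)
        assert max(TABLE2_VIFS[f] for f in retained) == pytest.approx(8.82)

    def test_single_exceedance_removed(self):
        assert apply_vif_threshold({"a": 11.0, "b": 2.0}, 10.0) == ["b"]

    def test_infinite_threshold_retains_everything(self):
        vifs = {"a": 11.0, "b": float("inf")}
        assert apply_vif_threshold(vifs, float("inf")) == ["a", "b"]


class TestSplitStandardize:
    def test_split_sizes_round_half_up(self, default_table):
        cfg = AnalyticsConfig(split_seed=1)
        out = split_standardize(default_table, "obesity_prev",
                                ["poverty", "unemployment"], cfg)
        x_tr, _, x_te = out[0], out[1], out[2]
        assert len(x_tr) == 151 and len(x_te) == 27

    def test_training_columns_standardized(self, default_table):
        cfg = AnalyticsConfig(split_seed=2)
        x_tr = split_standardize(default_table, "obesity_prev",
                                 ["poverty", "pct_black"], cfg)[0]
        np.testing.assert_allclose(x_tr.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(x_tr.std(axis=0), 1, atol=1e-12)

    def test_same_seed_same_membership(self, default_table):
        cfg = AnalyticsConfig(split_seed=3)
        a = split_standardize(default_table, "obesity_prev",
                              ["poverty"], cfg)
        b = split_standardize(default_table, "obesity_prev",
                              ["poverty"], cfg)
        np.testing.assert_array_equal(a[6], b[6])
        np.testing.assert_array_equal(a[7], b[7])


class TestSvrFit:
    def test_constant_outcome_gives_zero_weights(self, rng):
        x = rng.standard_normal((20, 3))
        m = fit_svr_linear(x, np.full(20, 5.0), c=1.0, epsilon=0.5)
        np.testing.assert_allclose(m.weights, 0, atol=1e-9)
        np.testing.assert_allclose(
            m.predict_standardized(x), 5.0, atol=0.5 + 1e-9
        )

    def test_noiseless_linear_data_recovers_ols(self, rng):
        x = rng.standard_normal((60, 4))
        beta = np.array([2.0, -1.0, 0.5, 3.0])
        y = x @ beta + 1.5
        m = fit_svr_linear(x, y, c=100.0, epsilon=1e-6)
        design = np.column_stack([np.ones(60), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(m.weights, coef[1:], atol=1e-3)
        np.testing.assert_allclose(m.intercept, coef[0], atol=1e-3)

    def test_objective_matches_independent_qp_solve(self, rng):
        """Primal objective agrees with an independent convex-QP solve
        (SLSQP on the slack formulation) to 1e-6 relative."""
        n, p = 30, 3
        rng = np.random.default_rng(3)  # fixed instance
        x = rng.standard_normal((n, p))
        y = x @ np.array([1.5, -2.0, 0.5]) + rng.normal(0, 0.3, n)
        c, eps = 2.0, 0.1
        m = fit_svr_linear(x, y, c, eps)
        obj_fit = svr_objective(m, x, y)
        a = np.hstack([x, np.ones((n, 1))])

        def f(z):
            return 0.5 * z[:p] @ z[:p] + c * z[p + 1:].sum()

        def jac(z):
            g = np.zeros_like(z)
            g[:p] = z[:p]
            g[p + 1:] = c
            return g

        cons = [
            {"type": "ineq",
             "fun": lambda z: z[p + 1:] - (y - a @ z[:p + 1]) + eps,
             "jac": lambda z: np.hstack([a, np.eye(n)])},
            {"type": "ineq",
             "fun": lambda z: z[p + 1:] + (y - a @ z[:p + 1]) + eps,
             "jac": lambda z: np.hstack([-a, np.eye(n)])},
        ]
        z0 = np.zeros(p + 1 + n)
        z0[p + 1:] = np.abs(y) + 1
        res = minimize(
            f, z0, jac=jac, constraints=cons, method="SLSQP",
            bounds=[(None, None)] * (p + 1) + [(0, None)] * n,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        # evaluate the hinge objective at the oracle's (w, b): a feasible
        # point's true objective, independent of slack slack accuracy
        w_or, b_or = res.x[:p], res.x[p]
        obj_oracle = 0.5 * w_or @ w_or + c * np.maximum(
            0.0, np.abs(y - (x @ w_or + b_or)) - eps
        ).sum()
        assert abs(obj_fit - obj_oracle) <= 1e-6 * (1 + abs(obj_oracle))


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        x = rng.standard_normal((40, 2))
        y = x @ np.array([1.0, 2.0]) + rng.normal(0, 0.1, 40)
        cfg = AnalyticsConfig(c_grid=(1.0,), epsilon_grid=(0.1,),
                              split_seed=0)
        best, table = grid_search_cv(x, y, cfg)
        assert best == (1.0, 0.1) and set(table) == {(1.0, 0.1)}

    def test_noiseless_fit_wins_with_near_zero_cv_rmse(self, rng):
        x = rng.standard_normal((50, 2))
        y = x @ np.array([1.0, -1.0]) + 3.0
        cfg = AnalyticsConfig(c_grid=(100.0,), epsilon_grid=(1e-6, 5.0),
                              split_seed=0)
        best, table = grid_search_cv(x, y, cfg)
        assert best == (100.0, 1e-6)
        assert table[best] < 1e-3

    def test_selected_point_matches_independent_recompute(self, rng):
        """2x2 grid winner equals the argmin of a CV table recomputed from
        scratch (folds, fits and RMSEs)."""
        x = rng.standard_normal((45, 3))
        y = x @ np.array([1.0, 0.5, -0.2]) + rng.normal(0, 0.5, 45)
        cfg = AnalyticsConfig(c_grid=(0.5, 2.0), epsilon_grid=(0.05, 0.3),
                              split_seed=9, cv_folds=5)
        best, table = grid_search_cv(x, y, cfg)
        folds = cv_folds(45, 5, 9)
        oracle = {}
        for c in cfg.c_grid:
            for eps in cfg.epsilon_grid:
                rmses = []
                for i in range(5):
                    hold = folds[i]
                    keep = np.concatenate(folds[:i] + folds[i + 1:])
                    m = fit_svr_linear(x[keep], y[keep], c, eps)
                    pred = m.predict_standardized(x[hold])
                    rmses.append(np.sqrt(np.mean((y[hold] - pred) ** 2)))
                oracle[(c, eps)] = np.mean(rmses)
        assert best == min(oracle, key=lambda k: (oracle[k], k[0], k[1]))
        for k in oracle:
            assert table[k] == pytest.approx(oracle[k], rel=1e-9)

    def test_winner_never_beaten_in_cv_table(self, rng):
        x = rng.standard_normal((40, 2))
        y = x @ np.array([2.0, 1.0]) + rng.normal(0, 1.0, 40)
        cfg = AnalyticsConfig(split_seed=4)
        best, table = grid_search_cv(x, y, cfg)
        assert all(table[best] <= v + 1e-15 for v in table.values())


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        x = rng.standard_normal((10, 2))
        y = x @ np.array([1.0, 1.0]) + 2.0
        m = fit_svr_linear(x, y, 100.0, 1e-6)
        rmse, r2 = evaluate(m, x, y)
        assert rmse == pytest.approx(0.0, abs=1e-3)
        assert r2 == pytest.approx(1.0, abs=1e-5)

    def test_hand_computed_three_point_case(self):
        from upho.analytics import SvrModel

        m = SvrModel(features=("x",), weights=np.array([0.0]),
                     intercept=0.0, C=1.0, epsilon=0.1,
                     scaling_mean=np.zeros(1), scaling_sd=np.ones(1))
        # predictions (1,2,4) for y=(1,2,3): residuals (0,0,1)
        x = np.array([[1.0], [2.0], [4.0]])
        m = SvrModel(features=("x",), weights=np.array([1.0]),
                     intercept=0.0, C=1.0, epsilon=0.1,
                     scaling_mean=np.zeros(1), scaling_sd=np.ones(1))
        rmse, r2 = evaluate(m, x, np.array([1.0, 2.0, 3.0]))
        assert rmse == pytest.approx(np.sqrt(1 / 3))
        assert r2 == pytest.approx(0.5)

    def test_zero_variance_outcome_rejected(self, rng):
        m = fit_svr_linear(rng.standard_normal((10, 1)),
                           rng.standard_normal(10), 1.0, 0.1)
        with pytest.raises(ValueError, match="zero-variance"):
            evaluate(m, rng.standard_normal((5, 1)), np.ones(5))


class TestImportance:
    def _model(self, weights):
        w = np.asarray(weights, dtype=float)
        from upho.analytics import SvrModel

        return SvrModel(features=tuple(f"f{i}" for i in range(len(w))),
                        weights=w, intercept=0.0, C=1.0, epsilon=0.1,
                        scaling_mean=np.zeros(len(w)),
                        scaling_sd=np.ones(len(w)))

    def test_scaled_spans_zero_to_hundred(self):
        imp = importance(self._model([3.0, -1.0, 0.5]))
        assert max(imp.scaled.values()) == 100.0
        assert min(imp.scaled.values()) == 0.0

    def test_equal_magnitudes_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="equal"):
            imp = importance(self._model([2.0, -2.0]))
        assert set(imp.scaled.values()) == {0.0}


class TestShapley:
    def _fitted(self, rng, p=5):
        n = 120
        x = rng.uniform(0, 100, (n, p))
        beta = rng.uniform(-0.5, 0.5, p)
        y = np.clip(x @ beta + 20 + rng.normal(0, 1, n), 0, 100)
        cols = [f"f{i}" for i in range(p)]
        table = pd.DataFrame(x, columns=cols)
        table["geoid"] = [f"47157{i:06d}" for i in range(n)]
        mean, sd = x.mean(axis=0), x.std(axis=0)
        m = fit_svr_linear((x - mean) / sd, y, 1.0, 0.1,
                           features=tuple(cols),
                           scaling_mean=mean, scaling_sd=sd)
        return m, table

    def test_background_mean_instance_has_zero_attribution(self, rng):
        m, table = self._fitted(rng)
        mean_row = table.drop(columns="geoid").mean()
        res = shapley_linear(m, mean_row, table)
        np.testing.assert_allclose(list(res.phi.values()), 0, atol=1e-9)

    def test_efficiency_for_every_instance(self, rng):
        m, table = self._fitted(rng)
        for _, row in table.head(20).iterrows():
            res = shapley_linear(m, row, table)
            assert sum(res.phi.values()) == pytest.approx(
                res.instance_prediction - res.baseline_prediction,
                abs=1e-9,
            )

    def test_matches_brute_force_coalition_oracle(self, rng):
        """Exhaustive interventional Shapley over all 2^5 coalitions."""
        m, table = self._fitted(rng, p=5)
        row = table.iloc[3]
        res = shapley_linear(m, row, table)
        cols = list(m.features)
        x = row[cols].to_numpy(dtype=float)
        bg = table[cols].to_numpy(dtype=float).mean(axis=0)

        def value(subset):
            v = bg.copy()
            v[list(subset)] = x[list(subset)]
            return float(m.predict_standardized(
                (v - m.scaling_mean) / m.scaling_sd))

        p = len(cols)
        for j, f in enumerate(cols):
            others = [k for k in range(p) if k != j]
            phi = 0.0
            for r in range(p):
                for s in itertools.combinations(others, r):
                    wgt = (math.factorial(len(s))
                           * math.factorial(p - len(s) - 1)
                           / math.factorial(p))
                    phi += wgt * (value(s + (j,)) - value(s))
            assert res.phi[f] == pytest.approx(phi, abs=1e-9)

    def test_missing_feature_rejected(self, rng):
        m, table = self._fitted(rng)
        with pytest.raises(ValueError, match="missing"):
            shapley_linear(m, {"f0": 1.0}, table)


class TestPipeline:
    def test_low_noise_defaults_reach_high_test_r2(self):
        cfg = GeneratorConfig(seed=21, outcome_weights=recovery_weights(),
                              outcome_noise_sd=1.0)
        res = run_analytics(generate_tracts(cfg))
        assert res.evaluation.r2_test >= 0.9

    def test_independent_features_all_screened_out(self, rng):
        n = 100
        table = pd.DataFrame({
            "geoid": [f"47157{i:06d}" for i in range(n)],
            "obesity_prev": rng.uniform(20, 60, n),
            "poverty": rng.uniform(0, 100, n),
            "unemployment": rng.uniform(0, 100, n),
        })
        with pytest.raises(PipelineError, match="Spearman"):
            run_analytics(table, features=["poverty", "unemployment"])

    def test_rerun_with_same_seeds_identical(self, default_table):
        a = run_analytics(default_table,
                          focus_geoid=default_table["geoid"].iloc[0])
        b = run_analytics(default_table,
                          focus_geoid=default_table["geoid"].iloc[0])
        assert a.to_json() == b.to_json()

    def test_summary_mentions_fit_quality(self, default_table):
        res = SdohSvr.from_dataframe(default_table).fit()
        s = res.summary()
        assert "R^2" in s and "epsilon" in s
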