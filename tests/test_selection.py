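"""Penalized selection machinery: closed forms, counts, stability."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from telomethyl import selection as sel
from telomethyl._penalized import ridge_path, coef_path, fit_at, lambda_grid


def _orthonormal_design(rng, n=60, p=8):
    """Mean-zero columns with X'X = I, for closed-form penalized solutions."""
    A = rng.standard_normal((n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q[:, :p]


class TestStandardize:
    def test_idempotent_and_affine_invariant(self, rng):
        X = pd.DataFrame(rng.normal(2.0, 3.0, (50, 4)), columns=list("abcd"))
        Z, mu, sd = sel.standardize(X)
        np.testing.assert_allclose(Z.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(ddof=1), 1, atol=1e-12)
        Z2, _, _ = sel.standardize(Z)
        np.testing.assert_allclose(Z2.to_numpy(), Z.to_numpy(), atol=1e-10)
        Z3, _, _ = sel.standardize(5.0 + 2.0 * X)
        np.testing.assert_allclose(Z3.to_numpy(), Z.to_numpy(), atol=1e-10)
        np.testing.assert_allclose((Z * sd + mu).to_numpy(), X.to_numpy(),
                                   atol=1e-10)

    def test_constant_column_named_in_error(self, rng):
        X = pd.DataFrame({"ok": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            sel.standardize(X)


class TestClosedForms:
    def test_ridge_matches_shrunken_ols_on_orthonormal_design(self, rng):
        X = _orthonormal_design(rng)
        n = X.shape[0]
        beta = rng.normal(size=X.shape[1])
        y = X @ beta + 0.1 * rng.standard_normal(n)
        lam = 0.3
        coefs, _ = ridge_path(X, y, np.array([lam]))
        expected = (X.T @ (y - y.mean())) / (1.0 + n * lam)
        np.testing.assert_allclose(coefs[:, 0], expected, atol=1e-6)

    def test_ridge_limits_to_ols(self, rng):
        X = _orthonormal_design(rng)
        y = X @ rng.normal(size=X.shape[1]) + 0.1 * rng.standard_normal(X.shape[0])
        coefs, _ = ridge_path(X, y, np.array([1e-12]))
        ols = np.linalg.lstsq(X, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(coefs[:, 0], ols, atol=1e-6)

    def test_lasso_equals_soft_threshold_on_orthonormal_design(self, rng):
        X = _orthonormal_design(rng)
        n = X.shape[0]
        y = X @ rng.normal(size=X.shape[1]) + 0.1 * rng.standard_normal(n)
        lam = 0.004
        _, coef = fit_at(X, y, 1.0, lam, tol=1e-10)
        xty = X.T @ (y - y.mean())
        expected = np.sign(xty) * np.maximum(np.abs(xty) - n * lam, 0.0)
        np.testing.assert_allclose(coef, expected, atol=1e-6)

    def test_objective_improves_on_zero_vector(self, rng):
        X = rng.standard_normal((80, 20))
        y = X[:, 0] * 2 + rng.standard_normal(80)
        lam, l1 = 0.05, 0.5
        b0, coef = fit_at(X, y, l1, lam)

        def objective(w, b):
            r = y - b - X @ w
            return (r @ r) / (2 * len(y)) + lam * (
                0.5 * (1 - l1) * w @ w + l1 * np.abs(w).sum())
        assert objective(coef, b0) < objective(np.zeros(20), y.mean())


class TestAdaptiveWeights:
    def test_duplicated_columns_get_equal_weights(self, rng):
        x = rng.standard_normal(80)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(80)})
        Z, _, _ = sel.standardize(X)
        y = x + rng.normal(0, 0.5, 80)
        a = sel.adaptive_weights(Z, y)
        assert a["a"] == pytest.approx(a["b"], rel=1e-6)

    def test_true_predictor_penalized_less_than_noise(self, rng):
        wins = 0
        for s in range(10):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.standard_normal((100, 5)),
                             columns=[f"x{j}" for j in range(5)])
            Z, _, _ = sel.standardize(X)
            y = 2.0 * Z["x0"].to_numpy() + r.standard_normal(100)
            a = sel.adaptive_weights(Z, y)
            wins += a["x0"] < a[["x1", "x2", "x3", "x4"]].min()
        assert wins >= 9

    def test_closed_form_on_orthonormal_design(self, rng):
        X = _orthonormal_design(rng)
        n = X.shape[0]
        y = X @ np.array([3.0, -2.0, 1.0, 0.5, 0, 0, 0, 0]) \
            + 0.05 * rng.standard_normal(n)
        cfg = sel.PenalizedFitConfig(seed=3)
        Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
        a = sel.adaptive_weights(Xdf, y, cfg)
        from telomethyl._penalized import cv_deviance
        cv = cv_deviance(X, y, 0.0, n_folds=cfg.n_folds, seed=cfg.seed,
                         n_lambda=cfg.n_lambda, min_ratio=cfg.lambda_min_ratio)
        expected = 1.0 / np.abs((X.T @ (y - y.mean())) / (1 + n * cv.lambda_min))
        np.testing.assert_allclose(a.to_numpy(), expected, rtol=1e-8)


class TestAdaptiveLasso:
    def test_equivalent_to_manually_rescaled_lasso(self, rng):
        X = pd.DataFrame(rng.standard_normal((90, 12)),
                         columns=[f"x{j}" for j in range(12)])
        Z, _, _ = sel.standardize(X)
        y = 2 * Z["x0"].to_numpy() - 1.5 * Z["x1"].to_numpy() \
            + rng.standard_normal(90)
        a = pd.Series(rng.uniform(0.5, 3.0, 12), index=Z.columns)
        cfg = sel.PenalizedFitConfig(seed=5)
        selected, coefs = sel.adaptive_lasso_select(Z, y, a, cfg)
        # independent route: rescale columns, plain sklearn Lasso at same lam
        from telomethyl._penalized import cv_deviance
        Xs = Z.to_numpy() / a.to_numpy()[None, :]
        cv = cv_deviance(Xs, y, 1.0, n_folds=cfg.n_folds, seed=cfg.seed,
                         n_lambda=cfg.n_lambda, min_ratio=cfg.lambda_min_ratio)
        las = Lasso(alpha=cv.lambda_1se, tol=1e-10).fit(Xs, y)
        np.testing.assert_allclose(coefs.to_numpy(), las.coef_ / a.to_numpy(),
                                   atol=1e-5)
        assert set(selected) == set(Z.columns[las.coef_ != 0])

    def test_huge_lambda_selects_nothing(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 6)))
        y = rng.standard_normal(50)
        _, coef = fit_at(X.to_numpy(), y, 1.0, 1e6)
        assert np.all(coef == 0)

    def test_bad_weights_rejected(self, rng):
        Z, _, _ = sel.standardize(pd.DataFrame(rng.standard_normal((30, 3))))
        a = pd.Series([1.0, -1.0, 2.0], index=Z.columns)
        with pytest.raises(ValueError, match="positive"):
            sel.adaptive_lasso_select(Z, rng.standard_normal(30), a)


class TestInteractions:
    @pytest.mark.parametrize("k,expected", [(208, 21_528), (247, 30_381), (2, 1)])
    def test_pair_counts(self, k, expected):
        ids = [f"cg{j:05d}" for j in range(k)]
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((3, k)),
                         columns=ids)
        block = sel.build_interactions(X, ids)
        assert block.shape[1] == expected

    def test_products_not_restandardized_and_ordered(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["b", "a", "c"])
        Z, _, _ = sel.standardize(X)
        block = sel.build_interactions(Z, ["b", "a", "c"])
        assert list(block.columns) == ["a:b", "a:c", "b:c"]
        np.testing.assert_allclose(block["a:b"],
                                   Z["a"].to_numpy() * Z["b"].to_numpy())
        assert block["a:b"].std(ddof=1) != pytest.approx(1.0, abs=1e-3)

    def test_single_id_yields_empty_block(self, rng):
        Z, _, _ = sel.standardize(pd.DataFrame(rng.standard_normal((10, 2)),
                                               columns=["a", "b"]))
        assert sel.build_interactions(Z, ["a"]).shape[1] == 0


class TestTermExpansion:
    def test_reference_counts_36_7_11(self):
        mains = [f"cg{j:05d}" for j in range(36)]
        new_members = [f"nv{j:02d}" for j in range(11)]
        pairs = [sel.interaction_id(mains[0], new_members[0]),
                 sel.interaction_id(mains[1], new_members[1]),
                 sel.interaction_id(new_members[2], new_members[3]),
                 sel.interaction_id(new_members[4], new_members[5]),
                 sel.interaction_id(new_members[6], new_members[7]),
                 sel.interaction_id(new_members[8], new_members[9]),
                 sel.interaction_id(new_members[10], mains[2])]
        exp_mains, inters = sel.expand_terms(mains, pairs)
        assert len(exp_mains) == 47
        assert len(exp_mains) + len(inters) == 54

    def test_no_interactions_is_identity(self):
        mains = ["a", "b", "c"]
        assert sel.expand_terms(mains, []) == (mains, [])

    def test_members_already_present_add_nothing(self):
        mains = ["a", "b", "c"]
        exp, _ = sel.expand_terms(mains, [sel.interaction_id("a", "c")])
        assert exp == mains


class TestTuning:
    def test_single_point_grid_returned(self, rng):
        X = rng.standard_normal((60, 5))
        y = X[:, 0] + rng.standard_normal(60)
        alpha, *_ = sel.tune_alpha(X, y, np.array([0.35]), seed=0)
        assert alpha == 0.35

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((80, 15))
        y = X[:, :3] @ np.ones(3) + rng.standard_normal(80)
        r1 = sel.tune_alpha(X, y, np.linspace(0, 1, 21), seed=11)
        r2 = sel.tune_alpha(X, y, np.linspace(0, 1, 21), seed=11)
        assert r1 == r2

    def test_dense_weak_effects_prefer_small_alpha(self):
        # many tiny equal effects: ridge-like mixing should win the deviance
        prefers = 0
        for s in range(5):
            r = np.random.default_rng(100 + s)
            X = r.standard_normal((100, 120))
            y = X @ np.full(120, 0.10) + r.standard_normal(100)
            alpha, *_ = sel.tune_alpha(X, y, np.array([0.05, 1.0]), seed=s)
            prefers += alpha == 0.05
        assert prefers >= 4


class TestStabilitySelection:
    def test_cohort_subsample_size(self):
        assert sel.subsample_size(247, 0.85) == 210

    @pytest.fixture(scope="class")
    def profile(self):
        r = np.random.default_rng(2)
        X = pd.DataFrame(r.standard_normal((80, 12)),
                         columns=[f"t{j}" for j in range(12)])
        y = 2.0 * X["t0"].to_numpy() + 1.6 * X["t1"].to_numpy() \
            + r.standard_normal(80)
        cfg = sel.PenalizedFitConfig(b_stability=25, seed=2)
        return sel.stability_selection(X, y, cfg), cfg, X, y

    def test_strong_terms_active_and_threshold_monotone(self, profile):
        prof, *_ = profile
        active95 = prof.active(0.95)
        assert {"t0", "t1"} <= set(active95)
        assert set(prof.active(1.0)) <= set(active95)

    def test_records_and_counts_consistent(self, profile):
        prof, cfg, _, _ = profile
        assert len(prof.records) == cfg.b_stability
        assert (prof.counts <= cfg.b_stability).all()
        np.testing.assert_allclose(prof.frequency,
                                   prof.counts / cfg.b_stability)

    def test_reproducible_under_seed(self, profile):
        prof, cfg, X, y = profile
        again = sel.stability_selection(X, y, cfg)
        pd.testing.assert_series_equal(prof.frequency, again.frequency)


class TestFinalFitAndBootstrap:
    @pytest.fixture(scope="class")
    def fitted(self):
        r = np.random.default_rng(9)
        X = pd.DataFrame(r.standard_normal((120, 6)),
                         columns=[f"t{j}" for j in range(6)])
        y = 1.8 * X["t0"].to_numpy() + r.standard_normal(120)
        model = sel.final_ridge_fit(X, y, sel.PenalizedFitConfig(seed=9))
        return model, X, y

    def test_r_squared_is_squared_pearson(self, fitted):
        model, _, y = fitted
        r = np.corrcoef(y, model.fitted)[0, 1]
        assert model.r_squared == pytest.approx(r * r, abs=1e-12)
        assert model.r_pearson == pytest.approx(r, abs=1e-12)

    def test_bootstrap_separates_signal_from_noise(self, fitted):
        model, X, y = fitted
        ps = sel.bootstrap_pvalues(model, X, y, b_bootstrap=200, seed=1)
        assert ps["t0"] == pytest.approx(1 / 200)
        assert ps.drop("t0").min() > 0.05

    def test_bootstrap_reproducible(self, fitted):
        model, X, y = fitted
        p1 = sel.bootstrap_pvalues(model, X, y, b_bootstrap=100, seed=5)
        p2 = sel.bootstrap_pvalues(model, X, y, b_bootstrap=100, seed=5)
        pd.testing.assert_series_equal(p1, p2)
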