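"""PLS engine: NIPALS correctness, cross-validation, component selection,
region focusing and bootstrap."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from qsar3d import (bootstrap_fit, fit_pls, group_cv, loo_cv, model_summary,
                    predict_activity, region_focus, select_onc)
from qsar3d import pls as pls_mod


def linear_data(rng, n=20, p=4, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_perfect_linear_fit(self, rng):
        X = rng.normal(size=(12, 2))
        y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.7
        m = fit_pls(X, y, 2)
        stats = model_summary(m, X, y)
        assert stats.r2 == pytest.approx(1.0, abs=1e-12)
        assert stats.see == pytest.approx(0.0, abs=1e-10)
        assert stats.f == np.inf

    def test_full_rank_equals_least_squares_oracle(self, rng):
        # 20 random instances; at c = rank(X), PLS = OLS
        for _ in range(20):
            X, y = linear_data(rng, n=8, p=4, noise=0.5)
            m = fit_pls(X, y, 4)
            A = np.column_stack([X, np.ones(8)])
            coef = np.linalg.lstsq(A, y, rcond=None)[0]
            ols_pred = A @ coef
            np.testing.assert_allclose(m.predict(X), ols_pred, atol=1e-8)

    def test_single_column_equals_simple_regression(self, rng):
        x = rng.normal(size=15)
        y = 2.0 * x + 1.0 + 0.3 * rng.normal(size=15)
        m = fit_pls(x[:, None], y, 1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert m.coef[0] == pytest.approx(slope, rel=1e-10)
        assert m.intercept == pytest.approx(intercept, rel=1e-10)

    def test_agrees_with_sklearn_nipals(self, rng):
        X, y = linear_data(rng, n=30, p=50, noise=0.4)
        for c in (1, 2, 3):
            m = fit_pls(X, y, c)
            sk = PLSRegression(n_components=c, scale=False).fit(X, y)
            np.testing.assert_allclose(m.predict(X), sk.predict(X).ravel(),
                                       atol=1e-8)

    def test_constant_y_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="constant"):
            fit_pls(X, np.ones(10), 1)

    def test_component_bounds_enforced(self, rng):
        X, y = linear_data(rng, n=6, p=3)
        with pytest.raises(ValueError, match="components"):
            fit_pls(X, y, 6)


class TestPredict:
    def test_training_rows_give_fitted_values(self, rng):
        X, y = linear_data(rng, noise=0.2)
        m = fit_pls(X, y, 3)
        np.testing.assert_array_equal(predict_activity(m, X), m.predict(X))

    def test_mean_row_predicts_training_mean(self, rng):
        X, y = linear_data(rng, noise=0.2)
        m = fit_pls(X, y, 2)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(y.mean())

    def test_duplicated_row_duplicated_prediction(self, rng):
        X, y = linear_data(rng)
        m = fit_pls(X, y, 2)
        two = m.predict(np.vstack([X[3], X[3]]))
        assert two[0] == two[1]

    def test_column_mismatch_rejected(self, rng):
        X, y = linear_data(rng)
        m = fit_pls(X, y, 2)
        with pytest.raises(ValueError, match="column"):
            m.predict(X[:, :2])


class TestLooCV:
    def test_noiseless_linear_gives_q2_near_one(self, rng):
        X, y = linear_data(rng, n=25, p=3, noise=0.0)
        assert loo_cv(X, y, 3).q2 >= 0.999

    def test_matches_brute_force_refit_oracle(self, rng):
        X, y = linear_data(rng, n=8, p=4, noise=0.6)
        c = 2
        res = loo_cv(X, y, c)
        press = 0.0
        for i in range(8):
            mask = np.arange(8) != i
            sk = PLSRegression(n_components=c, scale=False).fit(X[mask], y[mask])
            yi = sk.predict(X[i:i + 1]).ravel()[0]
            assert res.predictions[i] == pytest.approx(yi, abs=1e-8)
            press += (yi - y[i]) ** 2
        q2 = 1 - press / np.sum((y - y.mean()) ** 2)
        assert res.q2 == pytest.approx(q2, abs=1e-10)
        assert res.sep == pytest.approx(np.sqrt(press / (8 - c - 1)), abs=1e-8)

    def test_uninformative_x_gives_low_q2(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)  # independent of X
        assert loo_cv(X, y, 2).q2 < 0.3


class TestSelectOnc:
    def test_documented_trace_selects_two(self, monkeypatch):
        trace = {1: 0.50, 2: 0.57, 3: 0.58}

        def fake_loo(X, y, c):
            return pls_mod.CVResult(predictions=np.zeros(1), q2=trace[c],
                                    sep=0.0, n_components=c)
        monkeypatch.setattr(pls_mod, "loo_cv", fake_loo)
        onc, got = select_onc(np.zeros((20, 5)), np.arange(20.0), c_max=5)
        # 0.57 - 0.50 = 0.07 > 0.05 accepts 2; 0.01 < 0.057 rejects 3
        assert onc == 2
        assert got == [0.50, 0.57, 0.58]

    def test_decreasing_trace_selects_one(self, monkeypatch):
        trace = {1: 0.60, 2: 0.55, 3: 0.50}

        def fake_loo(X, y, c):
            return pls_mod.CVResult(predictions=np.zeros(1), q2=trace[c],
                                    sep=0.0, n_components=c)
        monkeypatch.setattr(pls_mod, "loo_cv", fake_loo)
        onc, _ = select_onc(np.zeros((20, 5)), np.arange(20.0), c_max=3)
        assert onc == 1

    def test_field_scenario_needs_more_than_one_component(self, fitted60_comsia):
        # three planted sites on five field blocks: one latent direction
        # cannot carry the whole signal, and the rule must notice
        _, res = fitted60_comsia
        onc, trace = select_onc(res.matrix, res.y_train, c_max=6)
        assert onc == res.onc >= 2
        # every accepted step cleared the 10% relative improvement bar
        for c in range(1, onc):
            assert trace[c] - trace[c - 1] > 0.10 * max(trace[c - 1], 0.01)


class TestGroupCV:
    def test_groups_equal_n_reduces_to_loo(self, rng):
        X, y = linear_data(rng, n=12, p=3, noise=0.4)
        g = group_cv(X, y, 2, groups=12, repeats=1, seed=0)
        l = loo_cv(X, y, 2)
        assert g.q2 == pytest.approx(l.q2, abs=1e-12)
        np.testing.assert_allclose(np.sort(g.predictions),
                                   np.sort(l.predictions), atol=1e-12)

    def test_same_seed_reproducible(self, rng):
        X, y = linear_data(rng, n=20, p=4, noise=0.5)
        a = group_cv(X, y, 2, groups=5, repeats=3, seed=7)
        b = group_cv(X, y, 2, groups=5, repeats=3, seed=7)
        assert a.q2 == b.q2 and a.sep == b.sep
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_noiseless_linear_data(self, rng):
        X, y = linear_data(rng, n=30, p=3, noise=0.0)
        assert group_cv(X, y, 3, groups=5, repeats=2, seed=1).q2 >= 0.999

    def test_too_many_groups_rejected(self, rng):
        X, y = linear_data(rng, n=10, p=3)
        with pytest.raises(ValueError, match="groups"):
            group_cv(X, y, 2, groups=11)


class TestBootstrap:
    def test_noiseless_fit_is_stable(self, rng):
        X, y = linear_data(rng, n=20, p=3, noise=0.0)
        b = bootstrap_fit(X, y, 3, B=30, seed=2)
        assert b.r2_mean == pytest.approx(1.0, abs=1e-10)
        assert b.r2_sd == pytest.approx(0.0, abs=1e-10)

    def test_reproducible_and_sd_nonnegative(self, rng):
        X, y = linear_data(rng, n=15, p=4, noise=0.8)
        a = bootstrap_fit(X, y, 2, B=50, seed=3)
        b = bootstrap_fit(X, y, 2, B=50, seed=3)
        assert (a.r2_mean, a.r2_sd) == (b.r2_mean, b.r2_sd)
        assert a.r2_sd >= 0 and a.see_sd >= 0


class TestRegionFocus:
    def test_zero_power_is_identity(self, fitted60_comsia):
        _, res = fitted60_comsia
        rf = region_focus(res.matrix, res.y_train, res.model, weight_power=0.0)
        np.testing.assert_allclose(rf.weights, 1.0, atol=1e-12)
        np.testing.assert_allclose(rf.model.coef, res.model.coef, atol=1e-10)
        assert rf.q2_after == pytest.approx(rf.q2_before, abs=1e-10)

    def test_improves_q2_on_shipped_scenario(self, fitted60_comsia):
        _, res = fitted60_comsia
        rf = region_focus(res.matrix, res.y_train, res.model, weight_power=1.0)
        assert rf.q2_after >= rf.q2_before

    def test_row_count_unchanged(self, fitted60_comsia):
        _, res = fitted60_comsia
        rf = region_focus(res.matrix, res.y_train, res.model)
        assert rf.matrix.n_compounds == res.matrix.n_compounds

    def test_negative_power_rejected(self, fitted60_comsia):
        _, res = fitted60_comsia
        with pytest.raises(ValueError, match="power"):
            region_focus(res.matrix, res.y_train, res.model, weight_power=-1.0)


class TestModelSummary:
    def test_four_point_hand_computation(self):
        # y on a single column; residuals computed by hand
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 1.1, 1.9, 3.0])
        m = fit_pls(X, y, 1)
        # simple regression: slope 0.99, intercept 0.015
        slope = np.cov(X[:, 0], y, ddof=1)[0, 1] / np.var(X[:, 0], ddof=1)
        resid = y - (slope * (X[:, 0] - 1.5) + y.mean())
        see_hand = np.sqrt(np.sum(resid ** 2) / (4 - 1 - 1))
        stats = model_summary(m, X, y)
        assert stats.see == pytest.approx(see_hand, rel=1e-10)
        r2_hand = 1 - np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2)
        assert stats.r2 == pytest.approx(r2_hand, rel=1e-12)
        assert stats.f == pytest.approx(r2_hand / (1 - r2_hand) * 2, rel=1e-10)

    def test_identical_blocks_split_contributions_evenly(self, fitted60_comsia):
        model, res = fitted60_comsia
        # duplicate one block by construction -> equal importance shares
        from qsar3d.fields import DescriptorMatrix
        X = res.matrix
        cols = X.block_columns("comsia_steric")
        Xdup = np.hstack([X.X[:, cols], X.X[:, cols]])
        m = fit_pls(Xdup, res.y_train, 2)
        dm = DescriptorMatrix(
            ids=list(X.ids), X=Xdup, calculator=X.calculator.__class__(
                spec=X.calculator.spec, kinds=("comsia_steric", "comsia_donor")),
            col_kind=np.array(["comsia_steric"] * len(cols)
                              + ["comsia_donor"] * len(cols)),
            col_point=np.concatenate([X.col_point[cols], X.col_point[cols]]),
            block_scale={"comsia_steric": 1.0, "comsia_donor": 1.0}, dropped=[])
        stats = model_summary(m, dm, res.y_train)
        assert stats.contributions["comsia_steric"] == pytest.approx(0.5, abs=1e-8)
        assert sum(stats.contributions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_contributions_sum_to_one(self, fitted60_comsia):
        _, res = fitted60_comsia
        assert sum(res.fit_stats.contributions.values()) == pytest.approx(1.0,
                                                                          abs=1e-9)


class TestNoiseRobustness:
    def test_noise_columns_do_not_inflate_q2(self, fitted60_comsia, rng):
        _, res = fitted60_comsia
        X, y = res.matrix.X, res.y_train
        q2_clean = loo_cv(X, y, res.onc).q2
        noise = rng.normal(scale=X.std(), size=(X.shape[0], 200))
        q2_noisy = loo_cv(np.hstack([X, noise]), y, res.onc).q2
        assert q2_noisy <= q2_clean + 0.05
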