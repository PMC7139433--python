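"""Penalized logistic solver: closed forms, oracles, KKT, path, LOSO selection."""

import numpy as np
import pytest
from scipy.special import expit, logit

from emomeg import (
    LambdaSelectionError,
    LassoLogisticLOSO,
    LassoLogisticRegression,
    fit_penalized_logit,
    lambda_path,
    loso_select_lambda,
    objective,
    predict_prob,
)
from emomeg.lasso import _fit_raw, _standardize_train, lambda_max, negative_log_likelihood


def brute_force_min(Xs, y, lam, span=5.0, refinements=2):
    """Coarse-to-fine grid minimization of the penalized objective (p == 2)."""
    g0 = g1 = g2 = np.arange(-span, span + 1e-9, 0.5)
    val = np.inf
    for _ in range(refinements + 1):
        B0, B1, B2 = np.meshgrid(g0, g1, g2, indexing="ij")
        eta = B0[..., None] + np.multiply.outer(B1, Xs[:, 0]) + np.multiply.outer(B2, Xs[:, 1])
        obj = np.sum(np.logaddexp(0, eta) - y * eta, axis=-1) + lam * (np.abs(B1) + np.abs(B2))
        idx = np.unravel_index(np.argmin(obj), obj.shape)
        best = (B0[idx], B1[idx], B2[idx])
        val = float(obj[idx])
        h = g0[1] - g0[0]
        g0 = np.linspace(best[0] - h, best[0] + h, 21)
        g1 = np.linspace(best[1] - h, best[1] + h, 21)
        g2 = np.linspace(best[2] - h, best[2] + h, 21)
    return val


def random_toy(rng, n=8, p=2, informative=True):
    X = rng.normal(size=(n, p))
    if informative:
        eta = X @ rng.normal(size=p)
        y = (rng.random(n) < expit(eta)).astype(float)
    else:
        y = (rng.random(n) < 0.5).astype(float)
    if y.min() == y.max():  # ensure both classes
        y[0] = 1.0 - y[0]
    return X, y


class TestPredictProb:
    def test_zero_model_gives_half(self):
        model = LassoLogisticRegression(lam=1.0, standardize=False)
        model.fit(np.array([[0.0], [1.0], [2.0], [3.0]]), np.array([0, 1, 0, 1]))
        model.coef_ = np.zeros(1)
        model.intercept_ = 0.0
        assert predict_prob(model, np.array([5.0])) == pytest.approx(0.5)

    def test_closed_form_value(self):
        model = LassoLogisticRegression(standardize=False)
        model.fit(np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]]),
                  np.array([0, 1, 0, 1]))
        model.coef_ = np.array([2.0, -1.0])
        model.intercept_ = 1.0
        # logistic(1 + 2 - 1) = logistic(2)
        assert predict_prob(model, np.array([1.0, 1.0])) == pytest.approx(
            expit(2.0), abs=1e-4
        )

    def test_monotone_in_linear_predictor_and_bounded(self):
        model = LassoLogisticRegression(standardize=False)
        model.fit(np.array([[0.0], [1.0], [2.0], [3.0]]), np.array([0, 0, 1, 1]))
        etas = [-1e3, -10, 0, 10, 1e3]
        model.coef_ = np.array([1.0])
        model.intercept_ = 0.0
        probs = [predict_prob(model, np.array([e])) for e in etas]
        assert np.all(np.diff(probs) >= 0)
        assert 0.0 < probs[0] and probs[-1] < 1.0

    def test_dimension_mismatch_errors(self):
        model = LassoLogisticRegression().fit(
            np.random.default_rng(0).normal(size=(10, 3)),
            np.array([0, 1] * 5),
        )
        with pytest.raises(ValueError):
            predict_prob(model, np.zeros(2))


class TestFit:
    def test_lambda_max_gives_null_model(self, labeled_noise_design):
        X, y = labeled_noise_design
        Xs, _, _ = _standardize_train(X)
        lmax = lambda_max(Xs, y)
        model = LassoLogisticRegression(lam=lmax).fit(X, y)
        assert model.n_nonzero_ == 0
        assert model.intercept_ == pytest.approx(logit(y.mean()), abs=1e-6)

    def test_lam_zero_matches_newton_ml(self):
        """Unpenalized fit agrees with an independent Newton solver."""
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 2))
        y = (rng.random(60) < expit(0.5 + X @ np.array([1.0, -0.7]))).astype(float)
        Xs, _, _ = _standardize_train(X)
        beta0, beta, _, _ = _fit_raw(Xs, y, 0.0)
        ref = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0).params
        assert np.max(np.abs(np.r_[beta0, beta] - ref)) < 1e-5

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle(self, seed):
        """Objective at the fit never exceeds the brute-force grid minimum."""
        rng = np.random.default_rng(100 + seed)
        X, y = random_toy(rng, n=int(rng.integers(6, 11)), p=2)
        Xs, _, _ = _standardize_train(X)
        lam = float(rng.uniform(0.05, 1.5))
        beta0, beta, _, _ = _fit_raw(Xs, y, lam)
        ours = objective(Xs, y, beta0, beta, lam)
        brute = brute_force_min(Xs, y, lam)
        assert ours <= brute + 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_kkt_conditions(self, seed):
        rng = np.random.default_rng(200 + seed)
        X, y = random_toy(rng, n=20, p=6)
        Xs, _, _ = _standardize_train(X)
        lam = 0.4 * lambda_max(Xs, y)
        beta0, beta, _, _ = _fit_raw(Xs, y, lam)
        pi = expit(beta0 + Xs @ beta)
        grad = Xs.T @ (y - pi)
        zero = beta == 0
        if np.any(zero):
            assert np.max(np.abs(grad[zero])) <= lam + 1e-5
        if np.any(~zero):
            assert np.allclose(grad[~zero], lam * np.sign(beta[~zero]), atol=1e-4)

    def test_matches_sklearn_saga(self, labeled_noise_design):
        """Independent L1 solver reaches the same objective value."""
        from sklearn.linear_model import LogisticRegression

        X, y = labeled_noise_design
        Xs, _, _ = _standardize_train(X)
        lam = 2.0
        sk = LogisticRegression(
            penalty="l1", C=1.0 / lam, solver="saga", max_iter=100_000, tol=1e-9
        ).fit(Xs, y)
        beta0, beta, _, _ = _fit_raw(Xs, y, lam)
        ours = objective(Xs, y, beta0, beta, lam)
        theirs = objective(Xs, y, float(sk.intercept_[0]), sk.coef_[0], lam)
        assert ours <= theirs + 1e-6
        assert ours == pytest.approx(theirs, abs=1e-4)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        X, y = random_toy(rng, n=12, p=2)
        Xs, _, _ = _standardize_train(X)
        lam = 0.3
        b0, b, _, _ = _fit_raw(Xs, y, lam)
        assert objective(Xs, y, b0, b, lam) == pytest.approx(
            objective(Xs, 1.0 - y, -b0, -b, lam), abs=1e-6
        )

    def test_separable_fit_warns_and_stays_finite(self):
        from sklearn.exceptions import ConvergenceWarning

        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(ConvergenceWarning):
            model = LassoLogisticRegression(lam=0.0).fit(X, y)
        assert np.all(np.isfinite(model.coef_))

    def test_negative_lam_rejected(self):
        with pytest.raises(ValueError):
            LassoLogisticRegression(lam=-1.0).fit(np.zeros((4, 1)), [0, 1, 0, 1])


class TestLambdaPath:
    def test_grid_shape_and_monotonicity(self, labeled_noise_design):
        X, y = labeled_noise_design
        grid = lambda_path(X, y)
        assert grid.size == 100
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(grid[0] * 1e-4, rel=1e-9)

    def test_nonzeros_zero_at_start_grow_along_path(self, labeled_noise_design):
        X, y = labeled_noise_design
        grid = lambda_path(X, y)
        Xs, _, _ = _standardize_train(X)
        b0, bstart, _, _ = _fit_raw(Xs, y, grid[0])
        assert np.count_nonzero(bstart) == 0
        b0, bend, _, _ = _fit_raw(Xs, y, grid[-1])
        assert np.count_nonzero(bend) >= np.count_nonzero(bstart)

    def test_constant_column_warns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array([0, 1] * 5)
        with pytest.warns(UserWarning, match="constant"):
            lambda_path(X, y)


class TestLosoSelection:
    def test_constraint_forces_two_nonzeros(self):
        """One dominant predictor: the constrained choice keeps >= 2 slopes."""
        rng = np.random.default_rng(62)
        n = 16
        y = np.array([0, 1] * (n // 2), dtype=float)
        strong = y * 2.0 - 1.0 + 0.9 * rng.normal(size=n)
        X = np.column_stack([strong, rng.normal(size=(n, 3))])
        sel = loso_select_lambda(X, y)
        assert sel.nonzero_counts[sel.chosen_index] >= 2
        assert sel.constraint_active
        assert sel.chosen_lam in sel.grid

    def test_pure_noise_deviance_near_null_level(self, labeled_noise_design):
        X, y = labeled_noise_design
        sel = loso_select_lambda(X, y)
        per_obs = sel.cv_deviance[sel.chosen_index]
        assert per_obs == pytest.approx(2 * np.log(2), rel=0.3)

    def test_planted_support_recovery(self):
        """Strong 2-channel effect: a planted channel is selected in >= 90% of seeds."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            y = np.concatenate([np.ones(17), np.zeros(16)])
            X = rng.normal(size=(33, 10))
            X[:, 0] += 2.5 * y
            X[:, 1] += 2.5 * y
            sel = loso_select_lambda(X, y)
            model = LassoLogisticRegression(lam=sel.chosen_lam).fit(X, y)
            support = set(np.flatnonzero(model.coef_))
            hits += bool(support & {0, 1})
        assert hits >= 0.9 * n_seeds

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            loso_select_lambda(np.zeros((2, 2)), np.array([0.0, 1.0]))

    def test_estimator_wrapper_delegates(self, labeled_noise_design):
        X, y = labeled_noise_design
        est = LassoLogisticLOSO().fit(X, y)
        assert est.lam_ == est.selection_.chosen_lam
        assert est.predict(X).shape == (33,)
        probs = est.predict_proba(X)
        assert np.all((probs > 0) & (probs < 1))


def test_functional_wrapper_equals_estimator(labeled_noise_design):
    X, y = labeled_noise_design
    a = fit_penalized_logit(X, y, lam=1.0)
    b = LassoLogisticRegression(lam=1.0).fit(X, y)
    assert np.allclose(a.coef_, b.coef_)
    assert negative_log_likelihood(X, y, a.intercept_, a.coef_) == pytest.approx(
        negative_log_likelihood(X, y, b.intercept_, b.coef_)
    )
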