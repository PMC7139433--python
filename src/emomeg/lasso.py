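"""L1-penalized logistic regression with leave-one-subject-out penalty selection.

The model is the standard binary logistic regression

    P(y = 1 | x) = exp(b0 + x'b) / (1 + exp(b0 + x'b))

fitted by minimizing the *summed* negative Bernoulli log-likelihood plus an
L1 penalty ``lam * sum(|b_m|)`` on the slopes (the intercept is never
penalized).  The solver is iteratively reweighted least squares with an
inner cyclic coordinate descent on the weighted quadratic surrogate —
every coordinate update is a closed-form soft-threshold step.  Convergence
is declared when the largest coefficient change in a full sweep falls below
``tol`` (default 1e-7) or after ``max_iter`` reweightings (default 1e4);
quasi-separated fits exit early on a likelihood plateau with bounded
coefficients and a warning.

Penalty selection follows the small-cohort protocol: a 100-point
log-spaced grid from the data-driven ``lambda_max`` (the smallest penalty
that zeroes every slope) down to ``1e-4 * lambda_max`` is scored by mean
held-out binomial deviance over leave-one-subject-out folds, and the
minimizer is taken among penalties whose full-data refit keeps at least two
nonzero slopes — sparse-but-not-univariate models.  Predictors are
standardized with training-fold statistics only.

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``) and composes with sklearn tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

COEF_BOUND = 50.0  # on the standardized scale; only reachable under separation
_PROB_EPS = 1e-12


@njit(cache=True)
def _cd_sweep_fit(X, y, lam, beta0, beta, tol, max_iter, bound):  # pragma: no cover
    """IRLS-coordinate-descent core for the L1-penalized logistic objective.

    Outer iterations refresh the exact gradient and the logistic weights
    ``pi (1 - pi)`` (floored at 1e-5); each inner pass is penalized
    weighted-least-squares coordinate descent (working residual updates
    only), first over all coordinates, then over the active set.  Runs in
    place on ``beta``.
    """
    n, p = X.shape
    eta = np.zeros(n)
    for i in range(n):
        s = beta0
        for j in range(p):
            if beta[j] != 0.0:
                s += X[i, j] * beta[j]
        eta[i] = s
    hit_bound = False
    n_iter = 0
    r = np.zeros(n)  # working residual y - pi - w * X (beta_new - beta_outer)
    w = np.zeros(n)  # IRLS weights pi (1 - pi), floored for stability
    wxsq = np.zeros(p)
    nll_prev = np.inf
    stall = 0
    for _ in range(max_iter):
        n_iter += 1
        nll = 0.0
        wsum = 0.0
        for i in range(n):
            e = eta[i]
            pi = 1.0 / (1.0 + np.exp(-e))
            r[i] = y[i] - pi
            wi = pi * (1.0 - pi)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            wsum += wi
            if e > 30.0:
                nll += e - y[i] * e
            elif e > -30.0:
                nll += np.log(1.0 + np.exp(e)) - y[i] * e
            else:
                nll += -y[i] * e
        if nll < 1e-8:
            # training data numerically perfectly fitted (separation)
            hit_bound = True
            break
        if nll_prev - nll < 1e-11 * (1.0 + nll):
            stall += 1
            if stall >= 3:
                # objective plateau: quasi-separation drives coefficients to
                # the bound with no likelihood gain; stop here
                if nll < 0.01 * n:
                    hit_bound = True  # training data essentially separated
                break
        else:
            stall = 0
        nll_prev = nll
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wxsq[j] = s
        outer_maxd = 0.0
        # inner CD on the weighted quadratic surrogate around (beta0, beta);
        # a loose cap suffices because the outer loop re-majorizes anyway
        for inner in range(20):
            maxd = 0.0
            full_sweep = inner == 0
            gsum = 0.0
            for i in range(n):
                gsum += r[i]
            d0 = gsum / wsum
            if d0 != 0.0:
                beta0 += d0
                for i in range(n):
                    r[i] -= w[i] * d0
            if abs(d0) > maxd:
                maxd = abs(d0)
            for j in range(p):
                if wxsq[j] <= 0.0:
                    continue
                if not full_sweep and beta[j] == 0.0:
                    continue
                g = 0.0
                for i in range(n):
                    g += X[i, j] * r[i]
                h = wxsq[j]
                z = h * beta[j] + g
                if z > lam:
                    bnew = (z - lam) / h
                elif z < -lam:
                    bnew = (z + lam) / h
                else:
                    bnew = 0.0
                if -1e-12 < bnew < 1e-12:
                    bnew = 0.0  # snap numerical dust so sparsity counts are exact
                if bnew > bound:
                    bnew = bound
                    hit_bound = True
                elif bnew < -bound:
                    bnew = -bound
                    hit_bound = True
                d = bnew - beta[j]
                if d != 0.0:
                    beta[j] = bnew
                    for i in range(n):
                        r[i] -= w[i] * d * X[i, j]
                if abs(d) > maxd:
                    maxd = abs(d)
            if maxd > outer_maxd:
                outer_maxd = maxd
            if maxd < tol:
                break
        # refresh the linear predictor exactly
        for i in range(n):
            s = beta0
            for j in range(p):
                if beta[j] != 0.0:
                    s += X[i, j] * beta[j]
            eta[i] = s
        if outer_maxd < tol:
            break
    return beta0, n_iter, hit_bound


def negative_log_likelihood(X, y, beta0, beta) -> float:
    """Summed Bernoulli negative log-likelihood at (beta0, beta)."""
    eta = beta0 + X @ beta
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def objective(X, y, beta0, beta, lam) -> float:
    """Penalized objective: summed NLL + lam * L1 norm of the slopes."""
    return negative_log_likelihood(X, y, beta0, beta) + lam * float(np.sum(np.abs(beta)))


def _standardize_train(X):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _fit_raw(Xs, y, lam, beta0=0.0, beta=None, tol=1e-7, max_iter=10_000):
    """Fit on already-standardized predictors; warm-startable."""
    Xs = np.ascontiguousarray(Xs, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    beta = np.zeros(Xs.shape[1]) if beta is None else np.ascontiguousarray(beta, dtype=np.float64)
    beta0, n_iter, hit_bound = _cd_sweep_fit(
        Xs, y, float(lam), float(beta0), beta, float(tol), int(max_iter), COEF_BOUND
    )
    return float(beta0), beta, int(n_iter), bool(hit_bound)


def lambda_max(Xs, y) -> float:
    """Smallest penalty at which every slope is exactly zero (standardized X)."""
    resid = y - y.mean()
    return float(np.max(np.abs(Xs.T @ resid)))


def lambda_path(
    X, y, n_lambdas: int = 100, lam_min_ratio: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced penalty grid from the data-driven ``lambda_max``.

    Constant predictor columns carry no information for the penalized fit and
    trigger a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(X.std(axis=0) == 0):
        warnings.warn("constant predictor columns detected; they will stay at zero")
    Xs, _, _ = _standardize_train(X)
    lmax = lambda_max(Xs, y)
    if lmax <= 0:
        raise ValueError("degenerate design: lambda_max is zero")
    return np.logspace(np.log10(lmax), np.log10(lmax * lam_min_ratio), n_lambdas)


class LassoLogisticRegression(ClassifierMixin, BaseEstimator):
    """Binary logistic regression with an L1 penalty on the slopes.

    Parameters
    ----------
    lam : float
        Penalty weight on the summed-likelihood scale (``lam = 0`` is the
        maximum-likelihood fit).
    standardize : bool
        Standardize predictors to zero mean / unit variance with training
        statistics; the stored standardization is applied at predict time.
    tol, max_iter : float, int
        Coordinate-descent stopping rule (max coefficient change / sweeps).

    Attributes
    ----------
    coef_ : (n_features,) slopes on the standardized predictor scale.
    intercept_ : float
    mean_, scale_ : stored standardization (zeros/ones when disabled).
    classes_ : the two class labels; the larger one is modeled as class 1.
    """

    def __init__(self, lam=1.0, standardize=True, tol=1e-7, max_iter=10_000):
        self.lam = lam
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("both classes must be present in y")
        y01 = (y == self.classes_[1]).astype(float)
        if self.standardize:
            Xs, self.mean_, self.scale_ = _standardize_train(np.asarray(X, dtype=float))
        else:
            Xs = np.asarray(X, dtype=float)
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        beta0, beta, n_iter, hit_bound = _fit_raw(
            Xs, y01, self.lam, tol=self.tol, max_iter=self.max_iter
        )
        if hit_bound:
            warnings.warn(
                "coefficients reached the solver bound; classes may be perfectly "
                "separable at this penalty",
                ConvergenceWarning,
            )
        self.intercept_ = beta0
        self.coef_ = beta
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return ((X - self.mean_) / self.scale_) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        with np.errstate(over="ignore"):
            p1 = 1.0 / (1.0 + np.exp(-eta))
        p1 = np.clip(p1, _PROB_EPS, 1.0 - _PROB_EPS)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(
            self.predict_proba(X)[:, 1] >= 0.5, self.classes_[1], self.classes_[0]
        )

    @property
    def n_nonzero_(self) -> int:
        check_is_fitted(self)
        return int(np.count_nonzero(self.coef_))


def fit_penalized_logit(X, y, lam, **kwargs) -> LassoLogisticRegression:
    """Functional wrapper over :class:`LassoLogisticRegression`."""
    return LassoLogisticRegression(lam=lam, **kwargs).fit(X, y)


def predict_prob(model: LassoLogisticRegression, x) -> float:
    """Probability of class 1 for a single predictor vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a single predictor vector")
    return float(model.predict_proba(x[None, :])[0, 1])


class LambdaSelectionError(RuntimeError):
    """No penalty on the grid satisfies the sparsity constraint."""


@dataclass
class LambdaSelection:
    """Outcome of leave-one-subject-out penalty selection."""

    grid: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_sd: np.ndarray
    nonzero_counts: np.ndarray
    chosen_lam: float
    chosen_index: int
    constraint_active: bool
    rule: str = "min"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) >= 0):
            raise ValueError("grid must be strictly decreasing")


def _heldout_deviance(eta, y) -> float:
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _path_fit(Xs, y, grid, tol, max_iter):
    """Warm-started fits along a descending penalty grid on standardized X."""
    p = Xs.shape[1]
    beta0, beta = 0.0, np.zeros(p)
    betas = np.empty((grid.size, p))
    beta0s = np.empty(grid.size)
    for k, lam in enumerate(grid):
        beta0, beta, _, _ = _fit_raw(Xs, y, lam, beta0, beta, tol, max_iter)
        betas[k] = beta
        beta0s[k] = beta0
    return beta0s, betas


def loso_select_lambda(
    X,
    y,
    n_lambdas: int = 100,
    lam_min_ratio: float = 1e-4,
    min_nonzero: int = 2,
    rule: str = "min",
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> LambdaSelection:
    """Pick the penalty by leave-one-subject-out cross-validated deviance.

    For every grid penalty the mean held-out binomial deviance over N
    one-subject folds is computed (fold-wise standardization, warm-started
    path fits), and the minimizer is returned among penalties whose
    *full-data* refit has at least ``min_nonzero`` nonzero slopes; ties go to
    the largest (sparsest) penalty.  ``constraint_active`` records whether
    the unconstrained minimizer was discarded.  ``rule="1sd"`` instead picks
    the largest eligible penalty within one standard deviation of the
    minimum deviance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out selection")
    for cls in (0.0, 1.0):
        if np.sum(y == cls) < 2:
            raise ValueError("both classes need at least 2 members")
    if rule not in ("min", "1sd"):
        raise ValueError("rule must be 'min' or '1sd'")

    grid = lambda_path(X, y, n_lambdas, lam_min_ratio)
    dev = np.zeros((n, grid.size))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xs, mean, scale = _standardize_train(X[mask])
        beta0s, betas = _path_fit(Xs, y[mask], grid, tol, max_iter)
        xi = (X[i] - mean) / scale
        eta = beta0s + betas @ xi
        for k in range(grid.size):
            dev[i, k] = _heldout_deviance(np.array([eta[k]]), np.array([y[i]]))
    mean_dev = dev.mean(axis=0)
    sd_dev = dev.std(axis=0, ddof=1) / np.sqrt(n)

    Xs_full, _, _ = _standardize_train(X)
    _, betas_full = _path_fit(Xs_full, y, grid, tol, max_iter)
    nonzero = np.count_nonzero(betas_full, axis=1)

    eligible = np.flatnonzero(nonzero >= min_nonzero)
    if eligible.size == 0:
        raise LambdaSelectionError(
            f"no penalty on the grid keeps >= {min_nonzero} nonzero coefficients"
        )
    unconstrained_idx = int(np.argmin(mean_dev))  # argmin takes the first = largest lam
    best_eligible = eligible[np.argmin(mean_dev[eligible])]
    if rule == "1sd":
        threshold = mean_dev[best_eligible] + sd_dev[best_eligible]
        best_eligible = eligible[np.flatnonzero(mean_dev[eligible] <= threshold)[0]]
    constraint_active = nonzero[unconstrained_idx] < min_nonzero

    return LambdaSelection(
        grid=grid,
        cv_deviance=mean_dev,
        cv_deviance_sd=sd_dev,
        nonzero_counts=nonzero,
        chosen_lam=float(grid[best_eligible]),
        chosen_index=int(best_eligible),
        constraint_active=bool(constraint_active),
        rule=rule,
    )


class LassoLogisticLOSO(ClassifierMixin, BaseEstimator):
    """LOSO-selected penalty followed by a full-data refit.

    ``fit`` runs :func:`loso_select_lambda` and refits
    :class:`LassoLogisticRegression` at the chosen penalty; the selection is
    kept in ``selection_`` and the refit model delegates prediction.
    """

    def __init__(
        self,
        n_lambdas=100,
        lam_min_ratio=1e-4,
        min_nonzero=2,
        rule="min",
        tol=1e-7,
        max_iter=10_000,
    ):
        self.n_lambdas = n_lambdas
        self.lam_min_ratio = lam_min_ratio
        self.min_nonzero = min_nonzero
        self.rule = rule
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("both classes must be present in y")
        y01 = (y == classes[1]).astype(float)
        self.selection_ = loso_select_lambda(
            X,
            y01,
            n_lambdas=self.n_lambdas,
            lam_min_ratio=self.lam_min_ratio,
            min_nonzero=self.min_nonzero,
            rule=self.rule,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.lam_ = self.selection_.chosen_lam
        self.model_ = LassoLogisticRegression(
            lam=self.lam_, tol=self.tol, max_iter=self.max_iter
        ).fit(X, y)
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.model_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self)
        return self.model_.predict_proba(X)

    def decision_function(self, X):
        check_is_fitted(self)
        return self.model_.decision_function(X)
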