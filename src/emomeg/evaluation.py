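"""Repeated stratified cross-validation with simultaneous confidence intervals.

Classifier performance on a small two-group cohort is summarized by
accuracy, sensitivity (true-positive rate for controls, class 1) and
specificity (true-negative rate for patients, class 0), estimated over many
repetitions of stratified k-fold cross-validation at a fixed penalty.  Per
repetition the held-out predictions of all folds are pooled into one metric
triple; medians and equal-tailed percentile intervals over repetitions are
reported.  Simultaneous coverage over several feature sets is obtained by
Bonferroni widening of the individual interval level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lasso import _fit_raw, _standardize_train, loso_select_lambda

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified CV settings."""

    k: int = 16
    reps: int = 1000
    lam: float = 1.0
    seed: int = 0
    m_hypotheses: int = 6
    simultaneous_level: float = 0.95
    nested: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0.0 < self.simultaneous_level < 1.0):
            raise ValueError("simultaneous_level must be in (0, 1)")
        if self.m_hypotheses < 1:
            raise ValueError("m_hypotheses must be >= 1")


@dataclass
class MetricDistribution:
    """Per-repetition metrics plus medians and simultaneous CIs."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    medians: dict
    ci_lower: dict
    ci_upper: dict
    individual_level: float

    def as_summary(self) -> dict:
        return {
            metric: {
                "median": self.medians[metric],
                "ci_lower": self.ci_lower[metric],
                "ci_upper": self.ci_upper[metric],
            }
            for metric in ("accuracy", "sensitivity", "specificity")
        }


def bonferroni_individual_level(simultaneous_level: float, m: int) -> float:
    """Individual interval level giving joint coverage over ``m`` hypotheses."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < simultaneous_level < 1.0):
        raise ValueError("simultaneous_level must be in (0, 1)")
    return 1.0 - (1.0 - simultaneous_level) / m


def percentile_ci(samples, individual_level: float) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    alpha = 1.0 - individual_level
    lo, hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Class-wise shuffled round-robin fold assignment.

    Within each class, subjects are shuffled and dealt round-robin; the deal
    cursor carries over between classes so overall fold sizes also differ by
    at most one.
    """
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects {n}")
    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=int)
    cursor = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        folds[perm] = (cursor + np.arange(perm.size)) % k
        cursor = (cursor + perm.size) % k
    return folds


def compute_metrics(y_true, y_pred, positive=1) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); positives are controls (class 1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_true == positive
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("a class is absent; its rate is undefined")
    correct = y_true == y_pred
    accuracy = float(correct.mean())
    sensitivity = float(correct[pos].mean())
    specificity = float(correct[~pos].mean())
    return accuracy, sensitivity, specificity


def _draw_valid_folds(y, k, seed, reps):
    """Fold assignment whose every training split contains both classes."""
    attempt_seed = seed
    for _ in range(100):
        folds = stratified_folds(y, k, attempt_seed)
        ok = all(
            np.unique(y[folds != f]).size == 2 for f in range(k)
        )
        if ok:
            return folds
        logger.warning("redrawing folds for seed %d: a training split lost a class", attempt_seed)
        attempt_seed += reps  # deterministic, disjoint from other repetitions
    raise RuntimeError("could not draw folds with both classes in every training split")


def repeated_cv(X, y, config: CVConfig, selector_kwargs: dict | None = None) -> MetricDistribution:
    """Repeated stratified k-fold CV of the penalized logistic classifier.

    Per repetition: fresh folds (seed ``config.seed + rep``); per fold the
    predictors are standardized on the training split and the model fitted at
    ``config.lam`` classifies the held-out subjects at probability threshold
    0.5.  All N held-out predictions of a repetition pool into one metric
    triple.  With ``config.nested`` the penalty is re-selected by LOSO inside
    every training split instead of being held fixed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    acc = np.empty(config.reps)
    sen = np.empty(config.reps)
    spe = np.empty(config.reps)
    for r in range(config.reps):
        folds = _draw_valid_folds(y, config.k, config.seed + r, config.reps)
        y_pred = np.empty(n)
        for f in range(config.k):
            train = folds != f
            lam = config.lam
            if config.nested:
                lam = loso_select_lambda(
                    X[train], y[train], **(selector_kwargs or {})
                ).chosen_lam
            Xs, mean, scale = _standardize_train(X[train])
            beta0, beta, _, _ = _fit_raw(Xs, y[train], lam)
            eta = ((X[folds == f] - mean) / scale) @ beta + beta0
            y_pred[folds == f] = (eta >= 0.0).astype(float)
        acc[r], sen[r], spe[r] = compute_metrics(y, y_pred)

    level = bonferroni_individual_level(config.simultaneous_level, config.m_hypotheses)
    metrics = {"accuracy": acc, "sensitivity": sen, "specificity": spe}
    medians = {k_: float(np.median(v)) for k_, v in metrics.items()}
    if config.reps >= 2:
        cis = {k_: percentile_ci(v, level) for k_, v in metrics.items()}
    else:
        cis = {k_: (float(v[0]), float(v[0])) for k_, v in metrics.items()}
    return MetricDistribution(
        accuracy=acc,
        sensitivity=sen,
        specificity=spe,
        medians=medians,
        ci_lower={k_: c[0] for k_, c in cis.items()},
        ci_upper={k_: c[1] for k_, c in cis.items()},
        individual_level=level,
    )
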