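"""Shrinkage-regularized linear discriminant analysis.

The decoder used throughout the pipeline: Gaussian classes with a shared
(pooled within-class) covariance, shrunk toward its diagonal to keep it
invertible when the channel count is large relative to the per-class trial
count.  The discriminant score of a point x for class k is the usual linear
form

    g_k(x) = x' Σ⁻¹ μ_k − ½ μ_k' Σ⁻¹ μ_k + log π_k

with Σ = (1−λ)·S_pooled + λ·diag(S_pooled).  Ties are broken toward the
lowest class label so predictions are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["LDAModel", "fit_lda", "predict_lda", "crossval_accuracy"]


@dataclass
class LDAModel:
    """Fitted discriminant model: class means, pooled covariance, priors."""

    class_labels: np.ndarray
    class_means: np.ndarray  # (n_classes, n_channels)
    pooled_covariance: np.ndarray  # after shrinkage
    shrinkage: float
    priors: np.ndarray
    _coef: np.ndarray = field(repr=False, default=None)  # (n_classes, n_channels)
    _intercept: np.ndarray = field(repr=False, default=None)

    @property
    def n_channels(self) -> int:
        return self.class_means.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores, samples × classes."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_channels:
            raise ValueError(
                f"X has {X.shape[1]} channels, model expects {self.n_channels}"
            )
        return X @ self._coef.T + self._intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        # argmax returns the first (lowest-label) maximum: deterministic ties.
        return self.class_labels[np.argmax(scores, axis=1)]


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float = 0.1,
    priors: np.ndarray | None = None,
) -> LDAModel:
    """Fit the shared-covariance Gaussian classifier.

    ``shrinkage`` in [0, 1] interpolates between the pooled empirical
    covariance (0) and its diagonal (1).  Priors default to empirical class
    frequencies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be samples × channels")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        lab = labels[counts.argmin()]
        raise ValueError(f"class {lab!r} has fewer than 2 samples")

    n, p = X.shape
    means = np.vstack([X[y == lab].mean(axis=0) for lab in labels])
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    idx = np.fromiter((label_to_idx[v] for v in y), count=n, dtype=np.int64)
    centered = X - means[idx]
    pooled = centered.T @ centered / (n - labels.size)
    cov = (1.0 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))

    if priors is None:
        priors = counts / n
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()

    try:
        # Solve Σ a_k = μ_k for each class via Cholesky (requires SPD).
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        if shrinkage == 0.0:
            raise ValueError(
                "pooled covariance is singular; use shrinkage > 0"
            ) from None
        # Degenerate (e.g. constant) features: a vanishing ridge keeps the
        # solve defined, reducing the classifier to its priors where the
        # data carry no signal.
        eps = 1e-9 * max(float(np.mean(np.diag(cov))), 1.0)
        chol = np.linalg.cholesky(cov + eps * np.eye(p))
    coef = np.linalg.solve(chol.T, np.linalg.solve(chol, means.T)).T
    intercept = -0.5 * np.einsum("kc,kc->k", coef, means) + np.log(priors)

    return LDAModel(
        class_labels=labels,
        class_means=means,
        pooled_covariance=cov,
        shrinkage=shrinkage,
        priors=priors,
        _coef=coef,
        _intercept=intercept,
    )


def predict_lda(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels (lowest label wins exact ties)."""
    return model.predict(X)


def crossval_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 20,
    n_repeats: int = 1,
    stratified: bool = True,
    seed: int | None = 0,
    shrinkage: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Stratified k-fold cross-validated classification accuracy.

    Returns ``(mean_accuracy, per_fold_accuracies)``; with ``n_repeats > 1``
    the partition is redrawn each repeat and folds are concatenated.  If the
    smallest class has fewer samples than ``n_folds``, the fold count is
    reduced to that size with a warning (at least 2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("every class needs at least 2 samples for cross-validation")
    folds = n_folds
    if min_count < n_folds:
        folds = min_count
        warnings.warn(
            f"reducing folds from {n_folds} to {folds}: smallest class has "
            f"{min_count} samples",
            RuntimeWarning,
            stacklevel=2,
        )
    if not stratified:
        raise NotImplementedError("only stratified cross-validation is supported")

    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_repeats):
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train, test in splitter.split(X, y):
            model = fit_lda(X[train], y[train], shrinkage=shrinkage)
            accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    per_fold = np.asarray(accs)
    return float(per_fold.mean()), per_fold
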