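"""Linear discriminant analysis with stratified k-fold cross-validation.

Two-class LDA on the band-ratio features: class-conditional Gaussians with
a shared (pooled) covariance give a linear decision boundary.  The pooled
covariance uses the unbiased n - K denominator and a small ridge term
lambda * I for numerical safety on near-collinear ratios.  The discriminant
score of class k at feature vector x is

    delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + ln pi_k

and the predicted class is the argmax; an exact tie is resolved to the
negative (healthy) class — the conservative choice for a diagnostic call.

Performance is reported as sensitivity (true-positive rate on tumor, the
positive class) and specificity (true-negative rate on healthy) of the
confusion matrix pooled over all held-out folds of a stratified k-fold
split; with ~50 measurements, per-fold rates are too coarse to average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import HEALTHY, TUMOR

__all__ = [
    "LDAModel",
    "ConfusionMatrix",
    "CVReport",
    "ClassifierError",
    "MODEL_CONFIGS",
    "fit_lda",
    "predict",
    "stratified_kfold",
    "cross_validate",
    "confusion_metrics",
]

#: Class order: index 0 = negative (healthy), index 1 = positive (tumor).
CLASSES = (HEALTHY, TUMOR)

#: Feature columns used by each model configuration.
MODEL_CONFIGS = {
    "drs": ["ratio1", "ratio2"],
    "af": ["ratio3", "ratio4"],
    "combined": ["ratio1", "ratio2", "ratio3", "ratio4"],
}

#: Default ridge: lambda = RIDGE_SCALE * trace(S) / d.
RIDGE_SCALE = 1e-8


class ClassifierError(ValueError):
    """Raised for invalid classifier inputs."""


@dataclass(frozen=True)
class LDAModel:
    """Fitted two-class LDA: per-class means, pooled covariance, priors."""

    classes: tuple[str, str]
    class_means: np.ndarray        # (K, d)
    pooled_covariance: np.ndarray  # (d, d), ridge already added
    priors: np.ndarray             # (K,)
    regularization_lambda: float

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.priors)) - 1.0) > 1e-12:
            raise ClassifierError("priors must sum to 1")
        if np.any(self.priors <= 0) or np.any(self.priors >= 1):
            raise ClassifierError("priors must lie strictly in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ClassifierError("X must be 2-D (n_samples, n_features)")
    if len(X) != len(y):
        raise ClassifierError("X and y length mismatch")
    if not np.all(np.isfinite(X)):
        raise ClassifierError("X contains missing or non-finite values")
    unknown = set(np.unique(y)) - set(CLASSES)
    if unknown:
        raise ClassifierError(f"unknown class labels {sorted(unknown)}")
    return X, y


def fit_lda(
    X: np.ndarray, y: np.ndarray, regularization_lambda: float | None = None
) -> LDAModel:
    """Fit two-class LDA with pooled (n - K denominator) covariance.

    ``regularization_lambda=None`` selects the default ridge
    ``1e-8 * trace(S) / d``; an explicit 0 disables it, in which case a
    singular covariance is an error suggesting a larger lambda.  Priors are
    the training class frequencies.
    """
    X, y = _validate_xy(X, y)
    n, d = X.shape
    means = np.empty((2, d))
    scatter = np.zeros((d, d))
    counts = np.empty(2)
    for k, cls in enumerate(CLASSES):
        Xk = X[y == cls]
        if len(Xk) < 2:
            raise ClassifierError(
                f"class {cls!r} has {len(Xk)} samples; need at least 2"
            )
        counts[k] = len(Xk)
        means[k] = Xk.mean(axis=0)
        centered = Xk - means[k]
        scatter += centered.T @ centered
    cov = scatter / (n - 2)
    if regularization_lambda is None:
        regularization_lambda = RIDGE_SCALE * float(np.trace(cov)) / d
    if regularization_lambda < 0:
        raise ClassifierError("regularization_lambda must be nonnegative")
    cov = cov + regularization_lambda * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ClassifierError(
            "pooled covariance is singular; raise regularization_lambda"
        ) from None
    return LDAModel(
        classes=CLASSES,
        class_means=means,
        pooled_covariance=cov,
        priors=counts / n,
        regularization_lambda=float(regularization_lambda),
    )


def predict(
    model: LDAModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and return per-sample discriminant scores (n, K).

    Deterministic: ties go to the first (healthy) class.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ClassifierError(
            f"feature dimension mismatch: model expects {model.n_features}"
        )
    # delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + ln pi_k
    sinv_mu = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # (d, K)
    scores = X @ sinv_mu
    scores -= 0.5 * np.einsum("kd,dk->k", model.class_means, sinv_mu)
    scores += np.log(model.priors)
    # np.argmax takes the first maximum, i.e. healthy on an exact tie
    labels = np.asarray(model.classes)[np.argmax(scores, axis=1)]
    return labels, scores


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Per-class shuffled round-robin fold assignment.

    Each class's members are spread across folds as evenly as possible
    (per-fold class counts differ by at most 1).  A pure function of
    (label order, k, seed).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ClassifierError(f"need k >= 2 folds, got {k}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ClassifierError(
                f"class {cls!r} has {len(idx)} samples; cannot stratify into "
                f"{k} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with tumor as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(tn+fp))."""
    if cm.tp + cm.fn == 0:
        raise ClassifierError("no positive (tumor) samples: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ClassifierError("no negative (healthy) samples: specificity undefined")
    return cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos_true = y_true == TUMOR
    pos_pred = y_pred == TUMOR
    return ConfusionMatrix(
        tp=int(np.sum(pos_true & pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )


@dataclass(frozen=True)
class CVReport:
    """Cross-validation result for one model configuration."""

    model_config: str
    seed: int
    k: int
    fold_assignments: np.ndarray
    per_fold: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    sensitivity: float
    specificity: float
    dropped_rows: int

    def to_dict(self) -> dict:
        return {
            "model_config": self.model_config,
            "seed": self.seed,
            "folds": self.k,
            "fold_assignments": self.fold_assignments.tolist(),
            "per_fold": [cm.to_dict() for cm in self.per_fold],
            "pooled_confusion": self.pooled.to_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dropped_rows": self.dropped_rows,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def cross_validate(
    table: pd.DataFrame,
    model_config: str,
    k: int = 5,
    seed: int = 0,
    regularization_lambda: float | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of one model configuration.

    ``model_config`` selects feature columns: ``"drs"`` -> (ratio1, ratio2),
    ``"af"`` -> (ratio3, ratio4), ``"combined"`` -> all four.  Rows missing
    any selected column are dropped (counted in the report).  The pooled
    confusion matrix collects every held-out prediction; sensitivity and
    specificity are computed from it.
    """
    if model_config not in MODEL_CONFIGS:
        raise ClassifierError(
            f"unknown model_config {model_config!r}; "
            f"choose from {sorted(MODEL_CONFIGS)}"
        )
    cols = MODEL_CONFIGS[model_config]
    subset = table[["tissue_label", *cols]].dropna()
    dropped = len(table) - len(subset)
    y = subset["tissue_label"].to_numpy()
    X = subset[cols].to_numpy(dtype=float)
    if len(set(np.unique(y)) & set(CLASSES)) < 2:
        raise ClassifierError(
            "need both healthy and tumor rows after dropping incomplete ones"
        )
    folds = stratified_kfold(y, k, seed)
    y_pred = np.empty_like(y)
    per_fold = []
    for f in range(k):
        held = folds == f
        model = fit_lda(X[~held], y[~held], regularization_lambda)
        y_pred[held], _ = predict(model, X[held])
        per_fold.append(_confusion(y[held], y_pred[held]))
    pooled = _confusion(y, y_pred)
    sens, spec = confusion_metrics(pooled)
    return CVReport(
        model_config=model_config,
        seed=seed,
        k=k,
        fold_assignments=folds,
        per_fold=per_fold,
        pooled=pooled,
        sensitivity=sens,
        specificity=spec,
        dropped_rows=dropped,
    )
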