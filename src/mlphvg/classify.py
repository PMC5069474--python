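"""Binary classification of two-dimensional network features.

Implements the two evaluation protocols used for the seizure-detection
experiment: leave-one-out cross-validation (one fit per sample) and
stratified 10-fold cross-validation repeated 10 times independently, with
the final accuracy the mean of the 10 per-repeat accuracies.  The
classifier is a support vector machine on features standardized with
statistics from the training portion only, so no test information leaks
into the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierConfig",
    "LabeledFeatureSet",
    "CVResult",
    "ProtocolError",
    "train_predict",
    "loocv",
    "repeated_kfold",
]


class ProtocolError(ValueError):
    """Raised when a cross-validation protocol's preconditions fail."""


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM settings; defaults are an RBF kernel on standardized features."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    standardize: bool = True


@dataclass(frozen=True)
class LabeledFeatureSet:
    """Rows of (signal_id, 2-D feature, binary label)."""

    signal_ids: tuple[str, ...]
    features: np.ndarray  # shape (n, 2)
    labels: np.ndarray  # values in {0, 1}

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if X.shape[0] != y.size or len(self.signal_ids) != y.size:
            raise ValueError("signal_ids, features and labels must align")
        if len(set(self.signal_ids)) != len(self.signal_ids):
            raise ValueError("duplicate signal_id")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)

    def __len__(self) -> int:
        return self.labels.size

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validation protocol run."""

    protocol: str
    accuracy: float
    predictions: np.ndarray | None = None  # per-sample labels (LOO)
    repeat_accuracies: np.ndarray | None = None  # per-repeat (k-fold)
    n_fits: int = 0
    seed: int | None = None


def _fit(train_X: np.ndarray, train_y: np.ndarray, config: ClassifierConfig):
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("svm", SVC(kernel=config.kernel, C=config.C, gamma=config.gamma))
    )
    model = Pipeline(steps)
    model.fit(train_X, train_y)
    return model


def train_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> np.ndarray:
    """Fit a maximum-margin classifier on the training rows and predict the
    test rows.

    Standardization statistics come from the training rows only.  A decision
    value of exactly 0 is broken toward class 0.  Degenerate training
    features (zero variance in every dimension) fall back to predicting the
    majority class, with a warning.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    test_X = np.asarray(test_X, dtype=float)
    if len(np.unique(train_y)) < 2:
        raise ProtocolError("training set must contain both classes")
    if np.allclose(train_X.var(axis=0), 0.0):
        warnings.warn(
            "degenerate training features (zero variance); predicting majority class",
            stacklevel=2,
        )
        counts = np.bincount(train_y, minlength=2)
        majority = 0 if counts[0] >= counts[1] else 1
        return np.full(test_X.shape[0], majority, dtype=int)
    model = _fit(train_X, train_y, config)
    dec = model.decision_function(test_X)
    # SVC orders classes [0, 1]: positive decision values mean class 1,
    # so an exact 0 falls to class 0.
    return (dec > 0).astype(int)


def loocv(
    features: LabeledFeatureSet,
    config: ClassifierConfig = ClassifierConfig(),
) -> CVResult:
    """Leave-one-out cross-validation: n train/predict rounds, one per
    held-out sample; accuracy is the fraction of correct predictions."""
    n0, n1 = features.class_counts()
    if n0 < 2 or n1 < 2:
        raise ProtocolError(
            f"leave-one-out needs >= 2 samples per class (got {n0}/{n1})"
        )
    n = len(features)
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        preds[i] = train_predict(
            features.features[mask],
            features.labels[mask],
            features.features[i : i + 1],
            config,
        )[0]
        mask[i] = True
    acc = float((preds == features.labels).mean())
    return CVResult(
        protocol="loo", accuracy=acc, predictions=preds, n_fits=n
    )


def repeated_kfold(
    features: LabeledFeatureSet,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
    stratified: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation repeated ``repeats`` times with
    independent random partitions; the final accuracy is the mean of the
    per-repeat accuracies.  Fully reproducible from ``seed``."""
    if k < 2:
        raise ProtocolError(f"k must be >= 2, got {k}")
    n0, n1 = features.class_counts()
    if min(n0, n1) < k and stratified:
        raise ProtocolError(
            f"k={k} exceeds the smaller class count ({min(n0, n1)})"
        )
    if n0 == 0 or n1 == 0:
        raise ProtocolError("both classes must be present")
    X, y = features.features, features.labels
    repeat_accs = np.empty(repeats, dtype=float)
    n_fits = 0
    for r in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=seed + r
        )
        groups = y if stratified else np.zeros_like(y)
        preds = np.empty(len(features), dtype=int)
        for train_idx, test_idx in splitter.split(X, groups):
            preds[test_idx] = train_predict(
                X[train_idx], y[train_idx], X[test_idx], config
            )
            n_fits += 1
        repeat_accs[r] = float((preds == y).mean())
    return CVResult(
        protocol="kfold",
        accuracy=float(repeat_accs.mean()),
        repeat_accuracies=repeat_accs,
        n_fits=n_fits,
        seed=seed,
    )
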