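"""Kernel MVPA: linear-kernel SVM / Gaussian process classifiers with
leave-one-subject-out cross-validation and the full performance metrics.

Features (one GBC map per subject) enter a linear kernel after
mean-centering computed on the training rows only; in cross-validation the
centering and every model fit are recomputed per fold from the training
subjects, so no information from the held-out subject leaks into training.

The multiclass Gaussian process classifier is a one-vs-rest combination of
binary Laplace GPCs with normalized class probabilities.  Ties in the
predicted class probability are broken by the fixed (sorted) class-label
order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.svm import SVC

from .gpc import LaplaceKernelGPC

__all__ = [
    "FeatureMatrix",
    "ModelSpec",
    "CVResult",
    "MetricsReport",
    "build_linear_kernel",
    "center_gram",
    "fit_predict",
    "run_losocv",
    "compute_metrics",
]

_ALGO_ALIASES = {
    "svm": "svm",
    "gpc": "gpc-binary",
    "gpc-binary": "gpc-binary",
    "gpc-multi": "gpc-multiclass",
    "gpc-multiclass": "gpc-multiclass",
}


@dataclasses.dataclass
class FeatureMatrix:
    """Subjects x voxels feature matrix with ids and group labels."""

    X: np.ndarray
    subject_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2D (subjects x voxels)")
        if len(self.subject_ids) != self.X.shape[0] or len(self.labels) != self.X.shape[0]:
            raise ValueError("subject ids / labels must match the row count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain missing or non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclasses.dataclass
class ModelSpec:
    algorithm: str = "svm"  # svm | gpc-binary | gpc-multiclass
    kernel: str = "linear"
    svm_cost: float = 1.0
    gpc_bias_variance: float = 1.0
    center_features: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGO_ALIASES:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.algorithm = _ALGO_ALIASES[self.algorithm]
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclasses.dataclass
class CVResult:
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # (n_subjects, n_classes)
    classes: np.ndarray
    scheme: str = "LOSOCV"

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("every subject must be predicted exactly once")
        if len(self.y_true) != n or len(self.y_pred) != n or self.scores.shape[0] != n:
            raise ValueError("per-fold arrays must cover every subject")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"subject_id": self.subject_ids, "y_true": self.y_true,
                           "y_pred": self.y_pred})
        for j, c in enumerate(self.classes):
            df[f"score_{c}"] = self.scores[:, j]
        return df

    def save(self, path: str | Path) -> None:
        payload = {"scheme": self.scheme, "classes": [str(c) for c in self.classes],
                   "folds": self.to_frame().to_dict(orient="records")}
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclasses.dataclass
class MetricsReport:
    """Per-class and overall performance, all values as fractions in [0, 1]."""

    classes: np.ndarray
    per_class: pd.DataFrame  # columns: sensitivity specificity accuracy ppv npv
    balanced_accuracy: float
    total_accuracy: float
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    roc_auc: float | None = None

    def to_percent_dict(self) -> dict:
        out = {
            "balanced_accuracy": 100.0 * self.balanced_accuracy,
            "total_accuracy": 100.0 * self.total_accuracy,
            "per_class": (100.0 * self.per_class).round(4).to_dict(orient="index"),
        }
        if self.roc_auc is not None:
            out["roc_auc"] = float(self.roc_auc)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_percent_dict(), indent=2, sort_keys=True))


def build_linear_kernel(X: np.ndarray, train_idx: np.ndarray | None = None,
                        center: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Linear kernel of rows centered by the training-row feature means.

    Returns (K, mu): K[i, j] = <x_i - mu, x_j - mu> with mu the mean of
    X[train_idx] (all rows when ``train_idx`` is None); mu is zero when
    ``center`` is False.
    """
    X = np.asarray(X, dtype=float)
    if center:
        if train_idx is not None and len(np.atleast_1d(train_idx)) == 0:
            raise ValueError("training set must not be empty")
        mu = X.mean(axis=0) if train_idx is None else X[train_idx].mean(axis=0)
    else:
        mu = np.zeros(X.shape[1])
    Xc = X - mu
    return Xc @ Xc.T, mu


def center_gram(G: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Training-mean centering applied directly to a raw Gram matrix.

    Algebraically identical to recomputing <x_i - mu, x_j - mu> with mu the
    train-row mean: K = G - m 1' - 1 m' + mm, m_i = mean_t G[i, t].
    """
    m = G[:, train_idx].mean(axis=1)
    mm = G[np.ix_(train_idx, train_idx)].mean()
    return G - m[:, None] - m[None, :] + mm


@dataclasses.dataclass
class FoldModel:
    """A fitted per-fold model; ``alpha`` are dual coefficients such that
    the primal weight vector is X_centered[train].T @ alpha (per class
    column for one-vs-rest multiclass)."""

    spec: ModelSpec
    classes: np.ndarray
    train_idx: np.ndarray
    alpha: np.ndarray  # (n_train,) binary or (n_train, n_classes) OvR
    intercept: float | np.ndarray
    _predictors: object = None

    def decision(self, K_test_train: np.ndarray) -> np.ndarray:
        return K_test_train @ self.alpha + self.intercept


def _fit_fold(spec: ModelSpec, K: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
              classes: np.ndarray) -> FoldModel:
    y_train = y[train_idx]
    present = np.unique(y_train)
    if len(present) < 2:
        raise ValueError("training set is degenerate: only one class present")
    Ktt = K[np.ix_(train_idx, train_idx)]

    if spec.algorithm == "svm":
        if len(classes) != 2:
            raise ValueError("binary SVM requires exactly 2 classes")
        svc = SVC(C=spec.svm_cost, kernel="precomputed")
        svc.fit(Ktt, y_train)
        alpha = np.zeros(len(train_idx))
        alpha[svc.support_] = svc.dual_coef_[0]
        return FoldModel(spec, classes, train_idx, alpha, float(svc.intercept_[0]), svc)

    if spec.algorithm == "gpc-binary" and len(classes) != 2:
        raise ValueError("binary GPC requires exactly 2 classes")

    # one-vs-rest Laplace GPCs (a single column for the binary case)
    cols = [classes[1]] if spec.algorithm == "gpc-binary" else list(classes)
    alphas, models = [], []
    for c in cols:
        yy = np.where(y_train == c, 1.0, -1.0)
        g = LaplaceKernelGPC(bias_variance=spec.gpc_bias_variance).fit(Ktt, yy)
        alphas.append(g.alpha_)
        models.append(g)
    alpha = alphas[0] if spec.algorithm == "gpc-binary" else np.column_stack(alphas)
    fm = FoldModel(spec, classes, train_idx, alpha,
                   intercept=0.0, _predictors=models)
    return fm


def _predict_fold(fm: FoldModel, K: np.ndarray, test_idx: np.ndarray,
                  classes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (predicted labels, (m, n_classes) scores) for the test rows."""
    Kst = K[np.ix_(test_idx, fm.train_idx)]
    if fm.spec.algorithm == "svm":
        dec = Kst @ fm.alpha + fm.intercept  # positive -> classes[1] (libsvm order)
        svc = fm._predictors
        pred = np.where(dec > 0, svc.classes_[1], svc.classes_[0])
        scores = np.column_stack([-dec, dec])
        if not np.array_equal(svc.classes_, classes):  # pragma: no cover
            order = [list(svc.classes_).index(c) for c in classes]
            scores = scores[:, order]
        return pred, scores

    diag = K[test_idx, test_idx]
    models = fm._predictors
    if fm.spec.algorithm == "gpc-binary":
        p1 = models[0].predict_proba(Kst, diag)
        scores = np.column_stack([1.0 - p1, p1])
    else:
        raw = np.column_stack([m.predict_proba(Kst, diag) for m in models])
        scores = raw / raw.sum(axis=1, keepdims=True)
    pred = classes[np.argmax(scores, axis=1)]  # argmax tie-break = class order
    return pred, scores


def fit_predict(model: ModelSpec, K: np.ndarray, y: np.ndarray,
                train_idx: np.ndarray, test_idx: np.ndarray,
                classes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training rows of a (centered) kernel and predict test rows.

    ``K`` must be the full kernel over all rows (train and test), centered
    consistently; scores are per-class (decision values for the SVM,
    probabilities for the GPCs).
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if classes is None:
        classes = np.unique(y[train_idx])
    fm = _fit_fold(model, K, np.asarray(y), train_idx, classes)
    return _predict_fold(fm, K, test_idx, classes)


def losocv_folds(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def _losocv_kernels(X: np.ndarray, center: bool) -> list[np.ndarray]:
    """Per-fold kernels, centered on each fold's training rows (via the
    Gram identity, so features are touched once)."""
    G = np.asarray(X, float) @ np.asarray(X, float).T
    n = G.shape[0]
    if not center:
        return [G] * n
    return [center_gram(G, np.delete(np.arange(n), i)) for i in range(n)]


def losocv_with_labels(fold_kernels: list[np.ndarray], y: np.ndarray, model: ModelSpec,
                       classes: np.ndarray,
                       collect_models: bool = False):
    """LOSOCV over precomputed per-fold kernels with an arbitrary label
    vector (the fast path shared with permutation testing)."""
    n = len(fold_kernels)
    y = np.asarray(y)
    preds = np.empty(n, dtype=y.dtype)
    scores = np.zeros((n, len(classes)))
    fms = []
    for i in range(n):
        train = np.delete(np.arange(n), i)
        fm = _fit_fold(model, fold_kernels[i], y, train, classes)
        p, s = _predict_fold(fm, fold_kernels[i], np.array([i]), classes)
        preds[i] = p[0]
        scores[i] = s[0]
        if collect_models:
            fms.append(fm)
    return preds, scores, fms


def run_losocv(features: FeatureMatrix, model: ModelSpec) -> CVResult:
    """Leave-one-subject-out CV with per-fold centering and fitting.

    Requires at least 2 subjects per class so every training fold contains
    both (all) classes.
    """
    classes = features.classes()
    counts = {c: int((features.labels == c).sum()) for c in classes}
    bad = [c for c, k in counts.items() if k < 2]
    if bad:
        raise ValueError(f"classes with fewer than 2 subjects: {bad}")
    kernels = _losocv_kernels(features.X, model.center_features)
    preds, scores, _ = losocv_with_labels(kernels, features.labels, model, classes)
    return CVResult(subject_ids=list(features.subject_ids), y_true=features.labels.copy(),
                    y_pred=preds, scores=scores, classes=classes)


def compute_metrics(cv: CVResult) -> MetricsReport:
    """Sensitivity/specificity/accuracy/PPV/NPV per class (one-vs-rest),
    balanced and total accuracy, and the pooled ROC for binary problems.

    Balanced accuracy is the unweighted mean of per-class recalls, which
    for two classes equals (sensitivity + specificity) / 2.
    """
    if len(cv.y_pred) != len(cv.y_true) or len(cv.y_true) == 0:
        raise ValueError("every subject needs a prediction")
    classes = cv.classes
    rows = {}
    for c in classes:
        tp = int(np.sum((cv.y_true == c) & (cv.y_pred == c)))
        tn = int(np.sum((cv.y_true != c) & (cv.y_pred != c)))
        fp = int(np.sum((cv.y_true != c) & (cv.y_pred == c)))
        fn = int(np.sum((cv.y_true == c) & (cv.y_pred != c)))
        rows[str(c)] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
            "ppv": tp / (tp + fp) if tp + fp else np.nan,
            "npv": tn / (tn + fn) if tn + fn else np.nan,
        }
    per_class = pd.DataFrame(rows).T
    balanced = float(per_class["sensitivity"].mean())
    total = float(np.mean(cv.y_true == cv.y_pred))

    fpr = tpr = area = None
    if len(classes) == 2:
        pos = classes[1]
        fpr, tpr, _ = roc_curve(cv.y_true == pos, cv.scores[:, 1])
        area = float(auc(fpr, tpr))
    return MetricsReport(classes=classes, per_class=per_class,
                         balanced_accuracy=balanced, total_accuracy=total,
                         roc_fpr=fpr, roc_tpr=tpr, roc_auc=area)
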