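"""Leave-one-out SVM classification over cluster-feature combinations.

``paper_loocv`` mode replicates the common single-loop procedure: an (C, gamma)
grid search in which each grid point is scored by whole-set LOOCV accuracy and
the best point's LOOCV predictions are reported.  Because the hyperparameters
see every fold, this estimate is optimistically biased; ``nested_loocv``
selects (C, gamma) inside each outer training fold and is the unbiased
variant.  Feature standardization is always fit on the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .io import PATIENT, SubjectRecord

__all__ = [
    "SvmConfig",
    "ClassifierReport",
    "confusion_metrics",
    "loocv_svm",
    "combination_search",
]


@dataclass
class SvmConfig:
    kernel: str = "rbf"
    log2c_range: tuple[float, float, float] = (-5, 15, 2)  # lo, hi, step
    log2g_range: tuple[float, float, float] = (-15, 3, 2)
    cv_mode: str = "paper_loocv"  # or "nested_loocv"

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"kernel must be rbf or linear, got {self.kernel!r}")
        if self.cv_mode not in ("paper_loocv", "nested_loocv"):
            raise ValueError(f"unknown cv_mode: {self.cv_mode!r}")
        for lo, hi, step in (self.log2c_range, self.log2g_range):
            if step <= 0 or hi < lo:
                raise ValueError("grid ranges must be nonempty with positive step")

    @property
    def c_grid(self) -> np.ndarray:
        lo, hi, step = self.log2c_range
        return 2.0 ** np.arange(lo, hi + 1e-9, step)

    @property
    def g_grid(self) -> np.ndarray:
        if self.kernel == "linear":
            return np.array([1.0])
        lo, hi, step = self.log2g_range
        return 2.0 ** np.arange(lo, hi + 1e-9, step)


@dataclass
class ClassifierReport:
    feature_set: str
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    counts: dict[str, int]
    best_log2c: float
    best_log2g: float
    cv_mode: str
    per_subject: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "counts": self.counts,
            "best_log2c": self.best_log2c,
            "best_log2g": self.best_log2g,
            "cv_mode": self.cv_mode,
            "per_subject": self.per_subject,
        }


def confusion_metrics(
    predictions: Sequence[int], labels: Sequence[int]
) -> tuple[float, float, float, dict[str, int]]:
    """Accuracy/sensitivity/specificity in percent with raw counts.

    Patients (label 1) are the positive class: sensitivity is patient
    detection, specificity control detection.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("empty or misaligned prediction/label vectors")
    pos = labels == 1
    neg = ~pos
    tp = int(np.sum(pos & (predictions == 1)))
    tn = int(np.sum(neg & (predictions == 0)))
    counts = {
        "correct_total": tp + tn,
        "total": int(labels.size),
        "true_pos": tp,
        "pos": int(pos.sum()),
        "true_neg": tn,
        "neg": int(neg.sum()),
    }
    acc = 100.0 * counts["correct_total"] / counts["total"]
    sens = 100.0 * tp / counts["pos"] if counts["pos"] else float("nan")
    spec = 100.0 * tn / counts["neg"] if counts["neg"] else float("nan")
    return acc, sens, spec, counts


def _loo_predictions(X: np.ndarray, y: np.ndarray, kernel: str, C: float, gamma: float) -> np.ndarray:
    """LOOCV predictions for fixed hyperparameters; the scaler is fit on each
    training fold only (test subjects never touch it)."""
    n = len(y)
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xte = (X[i : i + 1] - mu) / sd
        clf = SVC(kernel=kernel, C=C, gamma=gamma if kernel == "rbf" else "scale")
        clf.fit(Xtr, y[train])
        preds[i] = clf.predict(Xte)[0]
    return preds


def _grid_best(X: np.ndarray, y: np.ndarray, config: SvmConfig) -> tuple[float, float, np.ndarray]:
    """Best (C, gamma) by whole-set LOOCV accuracy; ties break on the first
    grid point in (C asc, gamma asc) order."""
    best = (-1.0, None, None, None)
    for C in config.c_grid:
        for g in config.g_grid:
            preds = _loo_predictions(X, y, config.kernel, C, g)
            acc = float(np.mean(preds == y))
            if acc > best[0]:
                best = (acc, C, g, preds)
    _, C, g, preds = best
    return float(C), float(g), preds


def _nested_predictions(X: np.ndarray, y: np.ndarray, config: SvmConfig) -> tuple[np.ndarray, float, float]:
    n = len(y)
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    chosen: list[tuple[float, float]] = []
    for i in range(n):
        train = idx != i
        C, g, _ = _grid_best(X[train], y[train], config)
        chosen.append((C, g))
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel=config.kernel, C=C, gamma=g if config.kernel == "rbf" else "scale")
        clf.fit((X[train] - mu) / sd, y[train])
        preds[i] = clf.predict((X[i : i + 1] - mu) / sd)[0]
    # report the modal hyperparameters across outer folds
    vals, counts = np.unique(np.array(chosen), axis=0, return_counts=True)
    C, g = vals[np.argmax(counts)]
    return preds, float(C), float(g)


def loocv_svm(
    features: np.ndarray,
    labels: Sequence[int] | Sequence[str],
    config: SvmConfig | None = None,
    feature_set: str = "all",
    subject_ids: Sequence[str] | None = None,
) -> ClassifierReport:
    """Leave-one-out SVM classification of patients vs controls.

    ``labels`` may be 0/1 integers or 'patient'/'control' strings.
    """
    config = config or SvmConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and len(labels) > 1:
        X = X.T
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = np.asarray([
        (1 if lab == PATIENT else 0) if isinstance(lab, str) else int(lab)
        for lab in labels
    ])
    if len(np.unique(y)) < 2 or min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("need at least 2 subjects per class")
    if config.cv_mode == "paper_loocv":
        C, g, preds = _grid_best(X, y, config)
    else:
        preds, C, g = _nested_predictions(X, y, config)
    acc, sens, spec, counts = confusion_metrics(preds, y)
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(len(y))]
    per_subject = [
        {"subject_id": sid, "true": int(t), "predicted": int(p)}
        for sid, t, p in zip(ids, y, preds)
    ]
    return ClassifierReport(
        feature_set=feature_set,
        accuracy_pct=round(acc, 2),
        sensitivity_pct=round(sens, 2),
        specificity_pct=round(spec, 2),
        counts=counts,
        best_log2c=float(np.log2(C)),
        best_log2g=float(np.log2(g)),
        cv_mode=config.cv_mode,
        per_subject=per_subject,
    )


def combination_search(
    feature_matrix: np.ndarray,
    labels: Sequence[int] | Sequence[str],
    config: SvmConfig | None = None,
    feature_names: Sequence[str] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> list[ClassifierReport]:
    """Evaluate every single cluster feature and every unordered pair
    (K + K(K-1)/2 runs), ranked by accuracy; ties break on higher sensitivity,
    then fewer features, then label order."""
    X = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if X.ndim != 2:
        raise ValueError("feature matrix must be subjects x clusters")
    K = X.shape[1]
    if K < 1:
        raise ValueError("need at least one cluster feature")
    names = list(feature_names) if feature_names is not None else [str(i + 1) for i in range(K)]
    subsets = [(i,) for i in range(K)] + list(combinations(range(K), 2))
    reports = []
    for subset in subsets:
        label = "".join(names[i] for i in subset)
        reports.append(
            loocv_svm(X[:, subset], labels, config, feature_set=label, subject_ids=subject_ids)
        )
    order = {id(r): i for i, r in enumerate(reports)}
    reports.sort(
        key=lambda r: (
            -r.accuracy_pct,
            -r.sensitivity_pct,
            len(r.feature_set),
            order[id(r)],
        )
    )
    return reports
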