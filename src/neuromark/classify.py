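"""Gaussian-kernel SVM with nested cross-validation.

The outer loop is leave-one-out: each subject is predicted by a model whose
feature selection, integration, standardization and hyperparameter tuning
saw only the remaining subjects. The inner loop is stratified fivefold
cross-validation over a logarithmic (C, gamma) grid for the soft-margin
radial-basis-function SVM; the kernel width h relates to gamma by
gamma = 1 / (2 h^2), so the default gamma grid spans the conventional
h range. Patients are the positive class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FeatureIntegrator, FeatureLayout

logger = logging.getLogger(__name__)

__all__ = [
    "KernelConfig",
    "TunedGaussianSVM",
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion_metrics",
    "loocv_evaluate",
]

DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**k) for k in range(-15, 4, 2))


@dataclass(frozen=True)
class KernelConfig:
    """Hyperparameter grid and inner-fold count for SVM tuning."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grid must be nonempty")


class TunedGaussianSVM(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with internal fivefold hyperparameter selection.

    ``fit`` standardizes features with training statistics, scores every
    (C, gamma) candidate by stratified inner cross-validation accuracy, and
    refits the winner on the whole training set. Ties are broken toward the
    smallest C, then the largest kernel width h (smallest gamma), i.e. the
    most regularized, smoothest candidate.
    """

    def __init__(
        self,
        config: KernelConfig = KernelConfig(),
        random_state: int = 0,
    ):
        self.config = config
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training fold contains a single class")
        cfg = self.config
        n_splits = min(cfg.inner_folds, *(int((y == c).sum()) for c in classes))
        if n_splits < 2:
            raise ValueError("need at least 2 subjects per class for inner CV")
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=self.random_state
        )
        C_grid = sorted(cfg.C_grid)
        gamma_grid = sorted(cfg.gamma_grid)  # ascending gamma = descending h
        correct = np.zeros((len(C_grid), len(gamma_grid)), dtype=int)
        for tr, te in skf.split(X, y):
            scaler = StandardScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
            for a, C in enumerate(C_grid):
                for b, gamma in enumerate(gamma_grid):
                    svc = SVC(kernel="rbf", C=C, gamma=gamma,
                              class_weight=cfg.class_weight).fit(Xtr, y[tr])
                    correct[a, b] += int((svc.predict(Xte) == y[te]).sum())
        # ties break toward the smallest C, then the smallest gamma (largest h)
        flat = np.argmax(correct)  # first occurrence in (C asc, gamma asc) order
        a, b = np.unravel_index(flat, correct.shape)
        self.inner_accuracy_ = correct[a, b] / X.shape[0]
        self.C_, self.gamma_ = C_grid[a], gamma_grid[b]
        self.h_ = 1.0 / np.sqrt(2.0 * self.gamma_)
        self.model_ = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=self.C_, gamma=self.gamma_,
                class_weight=cfg.class_weight),
        ).fit(X, y)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.atleast_2d(np.asarray(X, dtype=float)))

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(np.atleast_2d(np.asarray(X, dtype=float)))


@dataclass
class ConfusionMatrix:
    """Counts with patients as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def confusion_metrics(predictions, truths) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Accuracy, sensitivity and specificity as two-decimal percentages.

    accuracy = correct / total; sensitivity = TP / (TP + FN);
    specificity = TN / (TN + FP); patients are positives.
    """
    pred = np.asarray(predictions)
    truth = np.asarray(truths)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("predictions and truths must be equal-length and nonempty")
    pos_pred = pred == "patient" if pred.dtype.kind in "USO" else pred.astype(int) == 1
    pos_true = truth == "patient" if truth.dtype.kind in "USO" else truth.astype(int) == 1
    cm = ConfusionMatrix(
        TP=int(np.sum(pos_pred & pos_true)),
        FN=int(np.sum(~pos_pred & pos_true)),
        TN=int(np.sum(~pos_pred & ~pos_true)),
        FP=int(np.sum(pos_pred & ~pos_true)),
    )
    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 2) if den else float("nan")

    metrics = {
        "accuracy": pct(cm.TP + cm.TN, cm.n),
        "sensitivity": pct(cm.TP, cm.TP + cm.FN),
        "specificity": pct(cm.TN, cm.TN + cm.FP),
    }
    return cm, metrics


@dataclass
class ClassificationReport:
    """Per-subject LOOCV predictions plus confusion-derived metrics."""

    subject_ids: list[str]
    truths: list[str]
    predictions: list[str]
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: ConfusionMatrix
    fold_hyperparams: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "confusion": vars(self.confusion),
                "subjects": [
                    {"subject_id": s, "truth": t, "prediction": p}
                    for s, t, p in zip(self.subject_ids, self.truths, self.predictions)
                ],
                "fold_hyperparams": self.fold_hyperparams,
            },
            indent=2,
        )


def loocv_evaluate(
    X: np.ndarray,
    y,
    layout: FeatureLayout,
    subject_ids: list[str] | None = None,
    p_threshold: float = 0.008,
    kernel_config: KernelConfig = KernelConfig(),
    integrator_kwargs: dict | None = None,
    seed: int = 0,
) -> ClassificationReport:
    """Leave-one-out evaluation with fold-internal selection and tuning.

    For every held-out subject, a fresh :class:`FeatureIntegrator` (t-test /
    occurrence-test selection, PCA, cluster correction) and a fresh
    :class:`TunedGaussianSVM` are fitted on the remaining subjects only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n)]
    preds = []
    fold_params = []
    kwargs = integrator_kwargs or {}
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        integ = FeatureIntegrator(
            layout=layout, p_threshold=p_threshold, **kwargs
        ).fit(X[train], y[train])
        F_train = integ.transform(X[train])
        F_test = integ.transform(X[i][None, :])
        clf = TunedGaussianSVM(config=kernel_config, random_state=seed).fit(
            F_train, y[train]
        )
        preds.append(str(clf.predict(F_test)[0]))
        fold_params.append(
            {
                "held_out": subject_ids[i],
                "C": clf.C_,
                "gamma": clf.gamma_,
                "inner_accuracy": clf.inner_accuracy_,
                "n_partial_links": int(
                    integ.partial_.up_links_.size + integ.partial_.down_links_.size
                ),
                "n_spatial_links": int(integ.spatial_.selection_.selected.sum()),
                "n_pearson_links": int(integ.pearson_.columns_.size),
                "n_reho_voxels": int(integ.reho_.mask_.sum()),
                "n_falff_voxels": int(integ.falff_.mask_.sum()),
                "partial_up_links": integ.partial_.up_links_.tolist(),
                "partial_down_links": integ.partial_.down_links_.tolist(),
                "spatial_links": np.flatnonzero(
                    integ.spatial_.selection_.selected
                ).tolist(),
                "pearson_links": integ.pearson_.columns_.tolist(),
            }
        )
    cm, metrics = confusion_metrics(preds, y)
    return ClassificationReport(
        subject_ids=list(subject_ids),
        truths=[str(t) for t in y],
        predictions=preds,
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        confusion=cm,
        fold_hyperparams=fold_params,
    )
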