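"""Multiclass linear SVM on homotopic-connectivity features.

Features are the per-voxel Fisher-z values inside the abnormal-connectivity
ROIs plus age, sex, education and MMSE.  A filter step keeps a feature only
if all three pairwise two-sample t-tests (NC vs VMCI, NC vs MCI, VMCI vs
MCI) have p < 0.05 on the training rows; features are then z-scored with
training statistics, the SVM cost C is tuned on a log2 grid from 2^-8 to 2^3
in steps of 2^0.25 by stratified cross-validation (ties -> smallest C), and
a single one-vs-one linear-kernel model (LIBSVM via scikit-learn) is trained
once and applied unchanged to the external validation rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "select_features",
    "scale_unit_variance",
    "default_c_grid",
    "tune_c",
    "train_predict",
    "ClassReport",
    "report",
    "covariate_features",
]

logger = logging.getLogger(__name__)

CLASS_ORDER = ("NC", "VMCI", "MCI")


def select_features(X_train: np.ndarray, labels, alpha: float = 0.05) -> np.ndarray:
    """Boolean keep-mask: feature kept iff all three pairwise two-sample
    t-tests between the three classes give p < alpha."""
    X = np.atleast_2d(np.asarray(X_train, float))
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 3:
        raise ValueError(f"expected exactly 3 classes, got {list(levels)}")
    keep = np.ones(X.shape[1], dtype=bool)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = X[labels == levels[i]], X[labels == levels[j]]
            if len(a) < 2 or len(b) < 2:
                raise ValueError("each class needs n >= 2 for the t-test filter")
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p = stats.ttest_ind(a, b, axis=0)
            keep &= np.nan_to_num(p, nan=1.0) < alpha
    return keep


def scale_unit_variance(
    X_train: np.ndarray, X_val: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """z-score with training statistics only (mean and SD estimated on the
    training rows; validation rows are transformed with those same numbers,
    never their own).  Zero-variance training columns are dropped with a
    warning.  Returns (X_train_scaled, X_val_scaled, stats)."""
    X_train = np.atleast_2d(np.asarray(X_train, float))
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance feature(s) before scaling", int((~keep).sum()))
    scaled_train = (X_train[:, keep] - mean[keep]) / sd[keep]
    scaled_val = None
    if X_val is not None:
        X_val = np.atleast_2d(np.asarray(X_val, float))
        scaled_val = (X_val[:, keep] - mean[keep]) / sd[keep]
    return scaled_train, scaled_val, {"mean": mean[keep], "sd": sd[keep], "kept": keep}


def default_c_grid(exp_min: float = -8.0, exp_max: float = 3.0, exp_step: float = 0.25) -> np.ndarray:
    """Cost grid 2^e for e from exp_min to exp_max inclusive (45 values at
    the defaults)."""
    n = int(round((exp_max - exp_min) / exp_step)) + 1
    return 2.0 ** (exp_min + exp_step * np.arange(n))


def tune_c(
    X: np.ndarray,
    y,
    grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick C from the grid by stratified k-fold CV accuracy with a linear
    kernel; ties broken toward the smallest C; deterministic given the seed."""
    grid = default_c_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty C grid")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class to tune C")
    folds = min(n_folds, int(counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_c, best_acc = None, -np.inf
    for c in np.sort(grid):
        acc = cross_val_score(SVC(kernel="linear", C=float(c)), X, y, cv=cv).mean()
        if acc > best_acc + 1e-12:  # strict improvement only: ties keep the smaller C
            best_c, best_acc = float(c), acc
    return best_c


def train_predict(X_train: np.ndarray, y_train, X_val: np.ndarray, C: float) -> np.ndarray:
    """Train one one-vs-one linear-kernel SVM and apply it unchanged to the
    validation rows."""
    model = SVC(kernel="linear", C=float(C), decision_function_shape="ovo")
    model.fit(X_train, np.asarray(y_train))
    return model.predict(np.atleast_2d(np.asarray(X_val, float)))


@dataclass
class ClassReport:
    """Confusion matrix (rows = true, columns = predicted, in ``labels``
    order) with per-class precision/recall/F1 (fractions), overall accuracy
    and the chance baseline 1/#classes."""

    labels: tuple[str, ...]
    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    baseline: float
    never_predicted: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Per-class metrics in percent, as printed reports show them."""
        return pd.DataFrame(
            {
                "class": list(self.labels),
                "precision_pct": [round(100 * self.precision[c], 2) for c in self.labels],
                "recall_pct": [round(100 * self.recall[c], 2) for c in self.labels],
                "f1_pct": [round(100 * self.f1[c], 2) for c in self.labels],
            }
        )


def report(y_true, y_pred, labels: tuple[str, ...] = CLASS_ORDER) -> ClassReport:
    """Confusion matrix and derived metrics.

    precision_c = TP_c / predicted_c (0 with a flag if the class is never
    predicted), recall_c = TP_c / true_c, F1 the harmonic mean, accuracy the
    trace over the total, baseline 1/#classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    return report_from_confusion(conf, labels)


def report_from_confusion(confusion: np.ndarray, labels: tuple[str, ...] = CLASS_ORDER) -> ClassReport:
    """Metrics from an already-tabulated confusion matrix (rows = true)."""
    conf = np.asarray(confusion, dtype=int)
    if conf.shape != (len(labels), len(labels)):
        raise ValueError("confusion matrix shape does not match labels")
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    never = [lab for lab, n in zip(labels, pred_tot) if n == 0]
    precision = {lab: (tp[i] / pred_tot[i] if pred_tot[i] else 0.0) for i, lab in enumerate(labels)}
    recall = {lab: (tp[i] / true_tot[i] if true_tot[i] else 0.0) for i, lab in enumerate(labels)}
    f1 = {
        lab: (
            2 * precision[lab] * recall[lab] / (precision[lab] + recall[lab])
            if precision[lab] + recall[lab] > 0
            else 0.0
        )
        for lab in labels
    }
    return ClassReport(
        labels=tuple(labels),
        confusion=conf,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(tp.sum() / conf.sum()) if conf.sum() else 0.0,
        baseline=1.0 / len(labels),
        never_predicted=never,
    )


def covariate_features(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric [age, sex(M=1), education, MMSE] block in covariate-table row
    order."""
    sex = covariates["sex"].map({"M": 1.0, "F": 0.0}) if covariates["sex"].dtype == object else covariates["sex"]
    return np.column_stack(
        [
            covariates["age"].astype(float),
            sex.astype(float),
            covariates["education"].astype(float),
            covariates["mmse"].astype(float),
        ]
    )
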