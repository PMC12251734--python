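"""SVM movement-correctness classifier with leave-one-out evaluation.

The classifier is an RBF-kernel support vector machine (C = 1,
gamma = 1 / (n_features * feature_variance), i.e. sklearn's "scale") on
standardized features, with class weights inversely proportional to class
frequencies to absorb correct/incorrect imbalance.  Standardization is
refit inside every cross-validation fold so no information leaks from the
held-out unit.

Two LOOCV granularities exist: ``sample`` (each feature window held out
once — the reference protocol) and ``participant`` (leave one participant's
windows out — quantifies participant-level leakage).  Decision-boundary
ties predict class 1 (correct) for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import LeaveOneGroupOut, LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_COLUMNS


class SingleClassError(ValueError):
    """Training data (or a training fold) contains only one class."""


@dataclass(frozen=True)
class SVMParams:
    """Classifier hyperparameters (all exposed, defaults as documented)."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str | dict | None = "balanced"


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class CVReport:
    """Accuracy plus per-class precision/recall/F1/support and averages."""

    accuracy: float
    per_class: dict[int, ClassMetrics]
    macro_avg: ClassMetrics
    weighted_avg: ClassMetrics
    n_total: int

    def to_dict(self) -> dict:
        def cm(m: ClassMetrics) -> dict:
            return {"precision": m.precision, "recall": m.recall,
                    "f1": m.f1, "support": m.support}

        return {
            "accuracy": self.accuracy,
            "per_class": {str(k): cm(v) for k, v in self.per_class.items()},
            "macro_avg": cm(self.macro_avg),
            "weighted_avg": cm(self.weighted_avg),
            "n_total": self.n_total,
        }


def balanced_class_weights(y: np.ndarray) -> dict[int, float]:
    """Weights inversely proportional to class frequencies: n / (k * n_c)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n, k = len(y), len(classes)
    return {int(c): n / (k * cnt) for c, cnt in zip(classes, counts)}


def design_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, y, groups) from a feature table; groups are participant IDs."""
    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    groups = table["participant_id"].to_numpy()
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    return X, y, groups


def _make_pipeline(params: SVMParams) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=params.kernel, C=params.C, gamma=params.gamma,
                    class_weight=params.class_weight)),
    ])


def _predict(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Binary prediction with deterministic tie-break: boundary -> class 1."""
    df = model.decision_function(X)
    # sklearn orders decision values toward classes_[-1]; with labels {0, 1}
    # positive values mean class 1.
    return (df >= 0).astype(int)


def fit_classifier(table: pd.DataFrame, params: SVMParams | None = None) -> Pipeline:
    """Fit the standardize+SVM pipeline on a full feature table."""
    params = params or SVMParams()
    X, y, _ = design_matrix(table)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training data contains a single class")
    for c in (0, 1):
        if int(np.sum(y == c)) < 2:
            raise SingleClassError(f"need at least 2 rows of class {c}")
    return _make_pipeline(params).fit(X, y)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> CVReport:
    accuracy = float(np.mean(y_true == y_pred))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0)
    per_class = {
        c: ClassMetrics(float(prec[i]), float(rec[i]), float(f1[i]), int(supp[i]))
        for i, c in enumerate((0, 1))
    }
    n = int(supp.sum())
    macro = ClassMetrics(float(np.mean(prec)), float(np.mean(rec)),
                         float(np.mean(f1)), n)
    wts = supp / n
    weighted = ClassMetrics(float(np.sum(prec * wts)), float(np.sum(rec * wts)),
                            float(np.sum(f1 * wts)), n)
    return CVReport(accuracy=accuracy, per_class=per_class, macro_avg=macro,
                    weighted_avg=weighted, n_total=n)


def loocv(table: pd.DataFrame, granularity: str = "sample",
          params: SVMParams | None = None) -> CVReport:
    """Leave-one-out cross-validation over samples or participants.

    Every fold refits standardization and the SVM on the remaining units and
    predicts the held-out unit; predictions are pooled into one report.
    A training fold reduced to a single class raises
    :class:`SingleClassError` naming the fold.
    """
    params = params or SVMParams()
    X, y, groups = design_matrix(table)
    if len(y) < 3:
        raise ValueError("LOOCV needs at least 3 units")
    if granularity == "sample":
        splits = LeaveOneOut().split(X, y)
    elif granularity == "participant":
        splits = LeaveOneGroupOut().split(X, y, groups)
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    y_pred = np.empty_like(y)
    for fold, (train, test) in enumerate(splits):
        if len(np.unique(y[train])) < 2:
            raise SingleClassError(f"fold {fold}: training data has a single class")
        model = _make_pipeline(params).fit(X[train], y[train])
        y_pred[test] = _predict(model, X[test])
    return report_from_predictions(y, y_pred)


def holdout_eval(train: pd.DataFrame, test: pd.DataFrame,
                 params: SVMParams | None = None) -> CVReport:
    """Fit on ``train``, evaluate on ``test``; warns on participant overlap."""
    if len(test) == 0:
        raise ValueError("empty test set")
    overlap = set(train["participant_id"]) & set(test["participant_id"])
    if overlap:
        warnings.warn(
            f"train and test share participants {sorted(overlap)}; "
            "hold-out estimate may be optimistic", stacklevel=2)
    model = fit_classifier(train, params)
    X_test, y_test, _ = design_matrix(test)
    return report_from_predictions(y_test, _predict(model, X_test))


def report_to_table(report: CVReport) -> str:
    """Text table: per-class rows, accuracy, macro and weighted averages.

    Percentages are rounded to integers; the accuracy headline keeps two
    decimals.
    """
    def pct(x: float) -> str:
        return f"{round(x * 100):d}%"

    lines = [f"Average Accuracy: {report.accuracy * 100:.2f}%", ""]
    header = f"{'':>14}{'Precision':>12}{'Recall':>10}{'f1-Score':>12}{'Support':>10}"
    lines.append(header)
    for c in (0, 1):
        m = report.per_class[c]
        lines.append(f"{c:>14}{pct(m.precision):>12}{pct(m.recall):>10}"
                     f"{pct(m.f1):>12}{m.support:>10}")
    lines.append(f"{'accuracy':>14}{'':>12}{'':>10}{pct(report.accuracy):>12}"
                 f"{report.n_total:>10}")
    for name, m in (("macro avg", report.macro_avg), ("weighted avg", report.weighted_avg)):
        lines.append(f"{name:>14}{pct(m.precision):>12}{pct(m.recall):>10}"
                     f"{pct(m.f1):>12}{m.support:>10}")
    return "\n".join(lines)
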