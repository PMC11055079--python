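"""Regression metrics, detection metrics, ROC/AUC and correlation analysis.

Regression quality is summarised by MSE, MAE, RMSE and the R^2 score
R^2 = 1 - SS_res/SS_tot (negative values are meaningful — the model does
worse than predicting the mean — and are never clipped).  Detection uses
the standard confusion-matrix metrics with the anomaly as the positive
class.  ROC curves sweep the error score and AUC equals the Mann–Whitney
pair-ordering probability.  Pearson correlations between sensor channels
are binned into the conventional strength bands: weak |r| < 0.5, moderate
0.5 <= |r| < 0.7, strong |r| >= 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .simulate import SensorFrame

__all__ = [
    "RegressionMetrics",
    "DetectionMetrics",
    "ROCCurve",
    "CorrelationReport",
    "regression_metrics",
    "detection_metrics",
    "roc_auc",
    "classify_correlation",
    "correlation_analysis",
]


@dataclass
class RegressionMetrics:
    mse: float
    mae: float
    rmse: float
    r2: float | None  # None when the target has zero variance (undefined)

    def as_dict(self) -> dict:
        return {"mse": self.mse, "mae": self.mae, "rmse": self.rmse, "r2": self.r2}


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None  # None when nothing was flagged
    recall: float | None  # None when no positives exist in the labels
    f1: float | None
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "accuracy": self.accuracy,
        }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class CorrelationReport:
    matrix: pd.DataFrame  # symmetric Pearson matrix, unit diagonal
    classes: pd.DataFrame  # strength band per pair


def regression_metrics(y, y_hat) -> RegressionMetrics:
    """MSE, MAE, RMSE and R^2 of predictions against a reference series."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    if y.size == 0:
        raise ValueError("empty input")
    diff = y - y_hat
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - float(np.sum(diff**2)) / ss_tot
    return RegressionMetrics(mse, mae, rmse, r2)


def detection_metrics(labels, flags) -> DetectionMetrics:
    """Confusion-matrix metrics, anomaly = positive class.

    Degenerate cases are reported as ``None`` rather than silently as NaN:
    precision when nothing is flagged, recall when no true positives exist,
    F1 when either constituent is undefined or their sum is zero.
    """
    labels = np.asarray(labels, dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags are misaligned")
    tp = int(np.sum(labels & flags))
    fp = int(np.sum(~labels & flags))
    fn = int(np.sum(labels & ~flags))
    tn = int(np.sum(~labels & ~flags))
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / labels.size
    return DetectionMetrics(tp, fp, fn, tn, precision, recall, f1, accuracy)


def roc_auc(labels, scores, feature_names=None):
    """ROC curve(s) and AUC from anomaly scores.

    1-D inputs give a single :class:`ROCCurve` (raises if only one class is
    present).  2-D (T x F) inputs give a dict per feature; features whose
    label column is single-class map to ``None``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores are misaligned")
    if labels.ndim == 1:
        if len(np.unique(labels.astype(int))) < 2:
            raise ValueError("ROC needs both classes present")
        fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores)
        return ROCCurve(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))
    if feature_names is None:
        feature_names = tuple(f"feature_{i}" for i in range(labels.shape[1]))
    out = {}
    for i, name in enumerate(feature_names):
        col = labels[:, i].astype(int)
        if len(np.unique(col)) < 2:
            out[name] = None
            continue
        fpr, tpr, thr = _sk_roc_curve(col, scores[:, i])
        out[name] = ROCCurve(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))
    return out


def classify_correlation(r: float) -> str:
    """Strength band of a Pearson coefficient (boundaries 0.5 and 0.7
    belong to the stronger class)."""
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a < 0.5:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


def correlation_analysis(frame: SensorFrame) -> CorrelationReport:
    """Pearson matrix over sensor channels plus strength classes per pair.

    Constant columns yield undefined (NaN) coefficients, reported as the
    class ``"undefined"`` rather than dropped.
    """
    df = frame.to_dataframe()
    if len(df) < 2:
        raise ValueError("need at least two rows for correlations")
    matrix = df.corr(method="pearson")
    # pandas leaves the diagonal of constant columns as 1.0 only when
    # defined; force NaN diagonals of constant columns to stay visible
    classes = matrix.map(classify_correlation)
    return CorrelationReport(matrix, classes)
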