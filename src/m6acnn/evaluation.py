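"""Binary-classification metrics and cross-condition transfer evaluation.

Threshold metrics are the standard confusion-matrix summaries

    Sen = TP/(TP+FN)           Spe = TN/(TN+FP)
    Acc = (TP+TN)/N            MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

with MCC in [-1, 1] and the rest in [0, 1]; a zero denominator marks the
metric degenerate and reports 0. Threshold-free AUC (ROC) and AP
(precision-recall) round out the report. The transfer matrix applies every
condition-specific fitted model to every condition's independent test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "pr_ap",
    "evaluate",
    "cross_condition_matrix",
    "curve_points",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float | None = None
    ap: float | None = None
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "Sen": self.sen, "Spe": self.spe, "Acc": self.acc,
            "MCC": self.mcc, "AUC": self.auc, "AP": self.ap,
        }


def _check_labels_probs(labels: np.ndarray, probabilities: np.ndarray) -> tuple:
    labels = np.asarray(labels, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must have equal length")
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return labels, probabilities


def confusion(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Count TP/FP/TN/FN at a threshold; a tie (p == threshold) is called positive."""
    labels, probabilities = _check_labels_probs(labels, probabilities)
    pred = probabilities >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sen/Spe/Acc/MCC from confusion counts.

    Any metric with a zero denominator is reported as 0 and listed in
    ``degenerate`` rather than raising.
    """
    degenerate: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sen = ratio(c.tp, c.tp + c.fn, "Sen")
    spe = ratio(c.tn, c.tn + c.fp, "Spe")
    acc = ratio(c.tp + c.tn, c.total, "Acc")
    mcc_den = float(c.tp + c.fp) * (c.tn + c.fn) * (c.tp + c.fn) * (c.tn + c.fp)
    if mcc_den == 0:
        degenerate.append("MCC")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(mcc_den)
    return MetricsReport(sen, spe, acc, float(mcc), degenerate=tuple(degenerate))


def _check_both_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


def roc_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Area under the ROC curve (probability a positive outranks a negative;
    ties count one half)."""
    labels, probabilities = _check_labels_probs(labels, probabilities)
    _check_both_classes(labels)
    return float(roc_auc_score(labels, probabilities))


def pr_ap(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Average precision: step-wise area under the precision-recall curve."""
    labels, probabilities = _check_labels_probs(labels, probabilities)
    _check_both_classes(labels)
    return float(average_precision_score(labels, probabilities))


def evaluate(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full report: threshold metrics plus AUC and AP."""
    rep = metrics(confusion(labels, probabilities, threshold))
    return MetricsReport(
        rep.sen, rep.spe, rep.acc, rep.mcc,
        auc=roc_auc(labels, probabilities),
        ap=pr_ap(labels, probabilities),
        degenerate=rep.degenerate,
    )


def cross_condition_matrix(
    models: Mapping[str, object],
    testsets: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """AUC of every condition-specific model on every condition's test set.

    Rows are predictors (the fitted models), columns are datasets, matching
    the usual transfer-heatmap orientation. A model/testset pair with
    incompatible input shapes yields NaN with a warning.
    """
    conditions = list(testsets)
    out = pd.DataFrame(
        np.nan, index=list(models), columns=conditions, dtype=float
    )
    for mname, res in models.items():
        for cond in conditions:
            X, y = testsets[cond]
            try:
                probs = res.predict_proba(X)
            except ValueError as exc:
                warnings.warn(f"model {mname!r} on dataset {cond!r}: {exc}")
                continue
            out.loc[mname, cond] = roc_auc(y, probs)
    return out


def curve_points(
    labels: np.ndarray, probabilities: np.ndarray, kind: str = "roc"
) -> pd.DataFrame:
    """ROC or precision-recall curve points, ready for TSV export."""
    labels, probabilities = _check_labels_probs(labels, probabilities)
    _check_both_classes(labels)
    if kind == "roc":
        fpr, tpr, thr = roc_curve(labels, probabilities)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    if kind == "pr":
        prec, rec, thr = precision_recall_curve(labels, probabilities)
        return pd.DataFrame(
            {"recall": rec, "precision": prec,
             "threshold": np.append(thr, np.nan)}
        )
    raise ValueError("kind must be 'roc' or 'pr'")
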