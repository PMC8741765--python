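"""Confusion-matrix diagnostics for the binary DM / non_DM task.

Six metrics are reported: accuracy, precision, sensitivity (recall),
specificity, F1 and error rate, with DM the positive class.  Ratios
with a zero denominator are reported as NaN and flagged in
``MetricReport.undefined`` rather than silently coerced to 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1", "error_rate")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    error_rate: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def to_json(self) -> str:
        d = {k: (None if math.isnan(v) else v) for k, v in self.as_dict().items()}
        d["undefined"] = sorted(self.undefined)
        return json.dumps(d)


def confusion(
    predictions: Sequence[str], labels: Sequence[str], positive_class: str = "DM"
) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix with ``positive_class`` positive."""
    preds = np.asarray(predictions, dtype=object)
    labs = np.asarray(labels, dtype=object)
    if preds.shape != labs.shape:
        raise ConfigError(
            f"length mismatch: {preds.shape[0]} predictions vs {labs.shape[0]} labels"
        )
    pos_pred = preds == positive_class
    pos_lab = labs == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_pred & pos_lab)),
        fp=int(np.sum(pos_pred & ~pos_lab)),
        tn=int(np.sum(~pos_pred & ~pos_lab)),
        fn=int(np.sum(~pos_pred & pos_lab)),
    )


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if precision + sensitivity == 0:
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """The six standard diagnostics of a binary confusion matrix.

    ``error_rate`` is computed as ``1 - accuracy`` so the two always sum
    to exactly 1 (identical to (FP+FN)/total in exact arithmetic).
    """
    if cm.total < 1:
        raise ConfigError("confusion matrix is empty")
    undefined: set[str] = set()
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision = float("nan")
        undefined.add("precision")
    if cm.tp + cm.fn > 0:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = float("nan")
        undefined.add("sensitivity")
    if cm.tn + cm.fp > 0:
        specificity = cm.tn / (cm.tn + cm.fp)
    else:
        specificity = float("nan")
        undefined.add("specificity")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan")
        undefined.add("f1")
    else:
        f1 = f1_score(precision, sensitivity)
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        error_rate=1.0 - accuracy,
        undefined=frozenset(undefined),
    )


def roc_curve(
    scores: Sequence[float], labels: Sequence[str], positive_class: str = "DM"
) -> tuple[np.ndarray, float]:
    """ROC curve by descending-threshold sweep over the distinct scores.

    Ties are grouped; the returned (FPR, TPR) points run monotonically
    from (0, 0) to (1, 1) and the AUC is the trapezoid-rule area.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object) == positive_class
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group tied scores: cumulative counts at the last index of each group
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[ends]
    fps = np.cumsum(~y_sorted)[ends]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def report_table(rows: dict[str, MetricReport]) -> str:
    """Delimited table of metric reports, one model per row."""
    header = "model," + ",".join(METRIC_NAMES)
    lines = [header]
    for name, rep in rows.items():
        vals = ",".join(f"{getattr(rep, m):.3f}" for m in METRIC_NAMES)
        lines.append(f"{name},{vals}")
    return "\n".join(lines) + "\n"
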