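"""Confusion-matrix evaluation: per-class and macro precision/recall/F1.

Per class c (one-vs-rest on the K×K confusion matrix):

    TP = cm[c, c]             FN = row c minus TP
    FP = column c minus TP    TN = everything else

    accuracy  = (TP + TN) / n · 100
    precision = TP / (TP + FP) · 100
    recall    = TP / (TP + FN)          (unit scale)
    F1        = 2·P·R / (P + R) · 100   (P, R on unit scale)

All rates are computed on [0, 1] internally and scaled to percent only at
report time; recall is additionally echoed on the unit scale.  A class
with a zero denominator reports 0 with an explicit ``undefined`` flag so
reports are total functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PerClassMetrics",
    "confusion",
    "metrics_from_confusion",
]


@dataclass
class ConfusionMatrix:
    """K×K count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts).to_csv(path, index=False)


@dataclass
class PerClassMetrics:
    precision_pct: float
    recall: float  # unit scale
    recall_pct: float
    f1_pct: float
    support: int
    class_accuracy_pct: float  # one-vs-rest (TP+TN)/n
    undefined: list[str] = field(default_factory=list)


@dataclass
class MetricsReport:
    per_class: dict[str, PerClassMetrics]
    accuracy_pct: float  # multiclass trace(cm)/n
    macro_precision_pct: float
    macro_recall: float
    macro_recall_pct: float
    macro_f1_pct: float
    n_samples: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.per_class.items():
            rows.append({
                "class": name, "precision_pct": m.precision_pct,
                "recall": m.recall, "f1_pct": m.f1_pct, "support": m.support,
            })
        rows.append({
            "class": "__overall__", "precision_pct": self.macro_precision_pct,
            "recall": self.macro_recall, "f1_pct": self.macro_f1_pct,
            "support": self.n_samples,
        })
        return pd.DataFrame(rows)


def confusion(
    true: Sequence[int], pred: Sequence[int], K: int
) -> ConfusionMatrix:
    """Count matrix cm[t, p] = #{i : true_i = t, pred_i = p}."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    if len(true) and (true.min() < 0 or true.max() >= K
                      or pred.min() < 0 or pred.max() >= K):
        raise ValueError("labels outside [0, K)")
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts=counts)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics_from_confusion(
    cm: ConfusionMatrix, class_names: Sequence[str] | None = None
) -> MetricsReport:
    """Per-class one-vs-rest metrics and their macro averages."""
    counts = cm.counts
    k = cm.n_classes
    n = cm.n_samples
    if n == 0:
        raise ValueError("empty confusion matrix")
    names = list(class_names) if class_names is not None else [str(i) for i in range(k)]
    if len(names) != k:
        raise ValueError("class_names length must match matrix size")

    per_class: dict[str, PerClassMetrics] = {}
    precisions, recalls, f1s = [], [], []
    for c in range(k):
        tp = int(counts[c, c])
        fn = int(counts[c].sum() - tp)
        fp = int(counts[:, c].sum() - tp)
        tn = n - tp - fn - fp
        undefined: list[str] = []
        precision, p_undef = _safe_div(tp, tp + fp)
        if p_undef:
            undefined.append("precision")
        recall, r_undef = _safe_div(tp, tp + fn)
        if r_undef:
            undefined.append("recall")
        f1, f_undef = _safe_div(2 * precision * recall, precision + recall)
        if f_undef:
            undefined.append("f1")
        class_acc = (tp + tn) / n
        per_class[names[c]] = PerClassMetrics(
            precision_pct=precision * 100.0,
            recall=recall,
            recall_pct=recall * 100.0,
            f1_pct=f1 * 100.0,
            support=tp + fn,
            class_accuracy_pct=class_acc * 100.0,
            undefined=undefined,
        )
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)

    accuracy = np.trace(counts) / n
    return MetricsReport(
        per_class=per_class,
        accuracy_pct=accuracy * 100.0,
        macro_precision_pct=float(np.mean(precisions)) * 100.0,
        macro_recall=float(np.mean(recalls)),
        macro_recall_pct=float(np.mean(recalls)) * 100.0,
        macro_f1_pct=float(np.mean(f1s)) * 100.0,
        n_samples=n,
    )
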