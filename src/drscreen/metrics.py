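"""Confusion matrices and the one-vs-rest screening-metric suite.

For a K-class confusion matrix (rows = true class, columns = predicted),
each class c is scored one-vs-rest with

    TP = counts[c, c]            FN = row c  - TP
    FP = column c - TP           TN = total - TP - FN - FP

and the screening metrics

    sensitivity = TP / (TP + FN)      (true-positive rate)
    specificity = TN / (TN + FP)      (true-negative rate)
    PPV         = TP / (TP + FP)      (positive predictive value)
    NPV         = TN / (TN + FN)      (negative predictive value)
    F1          = 2 * PPV * sensitivity / (PPV + sensitivity)

plus overall accuracy = trace / total.  A zero denominator yields NaN
(the "undefined" flag), never an exception, so that classes absent from
small evaluation sets degrade gracefully.  In the binary case the
one-vs-rest views of the two classes are mirror images: sensitivity of
one class equals specificity of the other, and PPV of one equals NPV of
the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grading import GradeScheme

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "f1_score",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count table; rows = true class, columns = predicted class."""

    counts: np.ndarray
    scheme: GradeScheme

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.scheme)
        if counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} table, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("negative counts")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against all others."""
        i = self.scheme.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum()) - tp
        fp = int(self.counts[:, i].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn

    def to_frame(self) -> pd.DataFrame:
        classes = list(self.scheme.classes)
        return pd.DataFrame(self.counts, index=classes, columns=classes)


def confusion(
    true_labels: Sequence[str],
    predicted: Sequence[str],
    scheme: GradeScheme,
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into a confusion matrix."""
    if len(true_labels) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted)} predicted"
        )
    k = len(scheme)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted):
        counts[scheme.index(t), scheme.index(p)] += 1
    return ConfusionMatrix(counts, scheme)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def f1_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of PPV and sensitivity; NaN when undefined."""
    if math.isnan(ppv) or math.isnan(sensitivity):
        return math.nan
    den = ppv + sensitivity
    return 2.0 * ppv * sensitivity / den if den > 0 else math.nan


@dataclass(frozen=True)
class MetricsReport:
    """Per-class screening metrics plus overall accuracy.

    ``per_class[cls][metric]`` holds sensitivity / specificity / ppv /
    npv / f1; undefined values are NaN.
    """

    per_class: Mapping[str, Mapping[str, float]]
    accuracy: float
    scheme: GradeScheme
    n: int

    def __getitem__(self, cls: str) -> Mapping[str, float]:
        return self.per_class[cls]

    def metric(self, name: str, cls: str) -> float:
        if name == "accuracy":
            return self.accuracy
        return self.per_class[cls][name]

    def to_frame(self) -> pd.DataFrame:
        """Metrics as a (metric x class) frame, accuracy in the first row."""
        rows: dict[str, dict[str, float]] = {"accuracy": {}}
        for m in METRIC_NAMES:
            rows[m] = {
                c: self.per_class[c][m] for c in self.scheme.classes
            }
        rows["accuracy"] = {c: self.accuracy for c in self.scheme.classes}
        return pd.DataFrame(rows).T.loc[["accuracy", *METRIC_NAMES]]

    def to_text(self, precision: int = 4) -> str:
        """Aligned plain-text table: accuracy, then per-class metric rows."""
        label = {
            "sensitivity": "Sensitivity",
            "specificity": "Specificity",
            "f1": "F1 Score",
            "ppv": "PPV",
            "npv": "NPV",
        }
        lines = [f"accuracy\t{self.accuracy:.{precision}f}"]
        for m in ("sensitivity", "specificity", "f1", "ppv", "npv"):
            for c in self.scheme.classes:
                v = self.per_class[c][m]
                cell = "undefined" if math.isnan(v) else f"{v:.{precision}f}"
                lines.append(f"{label[m]} {c}\t{cell}")
        return "\n".join(lines)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest screening metrics for every class of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for cls in cm.scheme.classes:
        tp, fn, fp, tn = cm.one_vs_rest(cls)
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        ppv = _ratio(tp, tp + fp)
        npv = _ratio(tn, tn + fn)
        per_class[cls] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "npv": npv,
            "f1": f1_score(ppv, sens),
        }
    accuracy = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(per_class, accuracy, cm.scheme, cm.total)
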