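"""Confusion matrix and per-class evaluation indexes.

Rows of the matrix are the real category, columns the predicted category.
For each class Y (one-vs-rest): precision Ppr = TP/(TP+FP), sensitivity
Sen = TP/(TP+FN), specificity Spe = TN/(TN+FP), F1 = 2*Ppr*Sen/(Ppr+Sen)
and accuracy Acc = (TP+TN)/total.  Metrics are computed in exact rational
arithmetic and only rounded for display (one decimal on percentages,
half away from zero).  A zero denominator makes a metric *undefined*; it
is surfaced as such, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_io import CLASSES

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "micro_accuracy",
    "macro_average",
    "evaluation_report",
    "round_percent",
]


def round_percent(x, decimals: int = 1):
    """Percentage rounded half-away-from-zero; passes ``None`` through."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(x.numerator) / Decimal(x.denominator) if isinstance(x, Fraction) else Decimal(repr(float(x)))
    return float((d * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = real category, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = tuple(self.classes)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))
        df.index.name = "real"
        df.columns.name = "predicted"
        return df


@dataclass
class ClassMetrics:
    """One-vs-rest counts and indexes for a single class.

    Fraction-valued fields are exact rationals; ``None`` marks an
    undefined metric (zero denominator).
    """

    cls: str
    tp: int
    fp: int
    fn: int
    tn: int
    ppr: Fraction | None
    sen: Fraction | None
    spe: Fraction | None
    f1: Fraction | None
    acc: Fraction | None

    def as_percent_row(self) -> dict:
        return {
            "class": self.cls,
            "Ppr": round_percent(self.ppr),
            "Sen": round_percent(self.sen),
            "Spe": round_percent(self.spe),
            "F1": round_percent(self.f1),
            "Acc": round_percent(self.acc),
        }


def confusion_matrix(y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] = CLASSES) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #(true == classes[i] and pred == classes[j])``."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest metrics for ``cls``, exact until display rounding."""
    if cls not in cm.classes:
        raise ValueError(f"class {cls!r} not in matrix classes {cm.classes}")
    i = cm.classes.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    tn = cm.total - tp - fp - fn

    def ratio(num: int, den: int) -> Fraction | None:
        return Fraction(num, den) if den > 0 else None

    ppr = ratio(tp, tp + fp)
    sen = ratio(tp, tp + fn)
    spe = ratio(tn, tn + fp)
    if ppr is not None and sen is not None and (ppr + sen) > 0:
        f1 = 2 * ppr * sen / (ppr + sen)
    else:
        f1 = None
    acc = ratio(tp + tn, cm.total)
    return ClassMetrics(cls, tp, fp, fn, tn, ppr, sen, spe, f1, acc)


def micro_accuracy(cm: ConfusionMatrix) -> Fraction:
    """Trace over grand total: overall fraction of correct predictions."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return Fraction(int(np.trace(cm.counts)), cm.total)


def macro_average(values: Sequence) -> Fraction | float | None:
    """Unweighted mean over classes of one metric.

    Accepts exact Fractions, floats (e.g. re-entered printed percentages)
    or ``None``; any undefined input makes the average undefined.
    """
    vals = list(values)
    if not vals:
        raise ValueError("nothing to average")
    if any(v is None for v in vals):
        return None
    if all(isinstance(v, Fraction) for v in vals):
        return sum(vals, Fraction(0)) / len(vals)
    return float(np.mean([float(v) for v in vals]))


def evaluation_report(cm: ConfusionMatrix) -> "EvaluationReport":
    """Full report: the matrix, per-class metric rows and the average row."""
    per_class = [class_metrics(cm, c) for c in cm.classes]
    return EvaluationReport(cm, per_class)


@dataclass
class EvaluationReport:
    cm: ConfusionMatrix
    per_class: list[ClassMetrics]

    @property
    def micro_accuracy(self) -> Fraction:
        return micro_accuracy(self.cm)

    def metrics_frame(self) -> pd.DataFrame:
        """Per-class percentage table (1 decimal) plus the 'Average' row."""
        rows = [m.as_percent_row() for m in self.per_class]
        avg = {"class": "Average"}
        for key, attr in (("Ppr", "ppr"), ("Sen", "sen"), ("Spe", "spe"), ("F1", "f1"), ("Acc", "acc")):
            mean = macro_average([getattr(m, attr) for m in self.per_class])
            avg[key] = round_percent(mean)
        rows.append(avg)
        return pd.DataFrame(rows).set_index("class")

    def to_csv(self, matrix_path, metrics_path) -> None:
        self.cm.to_frame().to_csv(matrix_path)
        self.metrics_frame().to_csv(metrics_path)

    @staticmethod
    def matrix_from_csv(path) -> ConfusionMatrix:
        df = pd.read_csv(path, index_col=0)
        return ConfusionMatrix(df.to_numpy(dtype=np.int64), tuple(df.index))

    def __str__(self) -> str:
        fmt = lambda v: "undef" if v is None or v != v else f"{v:.1f}%"
        lines = ["Confusion matrix (rows = real, columns = predicted):"]
        lines.append(self.cm.to_frame().to_string())
        lines.append("")
        lines.append(f"{'class':<8}{'Ppr':>8}{'Sen':>8}{'Spe':>8}{'F1':>8}{'Acc':>8}")
        for row in self.metrics_frame().reset_index().to_dict("records"):
            lines.append(
                f"{row['class']:<8}" + "".join(f"{fmt(row[k]):>8}" for k in ("Ppr", "Sen", "Spe", "F1", "Acc"))
            )
        lines.append("")
        lines.append(f"Micro accuracy (trace/total): {float(self.micro_accuracy) * 100:.1f}%")
        return "\n".join(lines)
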