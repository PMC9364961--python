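"""Confusion-matrix construction and the staging metric suite.

All metrics derive from the 5x5 confusion matrix over the fixed stage order
(W, N1, N2, N3, REM), rows true, columns predicted.  Per class (one-vs-rest):
precision PRE = TP / (TP + FP), recall REC = TP / (TP + FN), and
F1 = 2 * PRE * REC / (PRE + REC).  Overall accuracy ACC is the matrix trace
over the total count, and MF1 is the unweighted mean of the five per-class
F1 values.

Zero-division convention: an empty predicted class has PRE = 0; an absent
true class has REC = F1 = 0 and (by default) still enters the MF1 average.
Metrics are fractions in [0, 1] programmatically and percentages in
reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .stages import N_STAGES, STAGE_ORDER, StageLabel

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "per_class_metrics",
    "accuracy",
    "macro_f1",
    "report",
]


@dataclass
class ConfusionMatrix:
    """5x5 integer count matrix, rows = true stage, cols = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"counts must be {N_STAGES}x{N_STAGES}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float


def confusion(
    y_true: Sequence[StageLabel], y_pred: Sequence[StageLabel]
) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(true == i and predicted == j)."""
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if len(y_true) == 0:
        raise ValueError("need at least one scored epoch")
    counts = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    ti = np.array([int(t) for t in y_true])
    pi = np.array([int(p) for p in y_pred])
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts)


def per_class_metrics(cm: ConfusionMatrix) -> dict[StageLabel, ClassMetrics]:
    """One-vs-rest precision, recall and F1 for each of the five stages."""
    counts = cm.counts
    out: dict[StageLabel, ClassMetrics] = {}
    for k, stage in enumerate(STAGE_ORDER):
        tp = float(counts[k, k])
        fp = float(counts[:, k].sum() - counts[k, k])
        fn = float(counts[k, :].sum() - counts[k, k])
        pre = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * pre * rec / (pre + rec) if pre + rec > 0 else 0.0
        out[stage] = ClassMetrics(precision=pre, recall=rec, f1=f1)
    return out


def accuracy(cm: ConfusionMatrix) -> float:
    """Correctly scored fraction: matrix trace over the total count."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def macro_f1(
    cm: ConfusionMatrix, *, include_absent_classes: bool = True
) -> float:
    """Unweighted mean of the per-class F1 values.

    With ``include_absent_classes=False``, classes with no true examples
    are left out of the average instead of contributing F1 = 0.
    """
    metrics = per_class_metrics(cm)
    if include_absent_classes:
        values = [m.f1 for m in metrics.values()]
    else:
        present = cm.counts.sum(axis=1) > 0
        values = [m.f1 for k, m in enumerate(metrics.values()) if present[k]]
        if not values:
            return 0.0
    return float(np.mean(values))


def report(
    cm: ConfusionMatrix,
    out_dir: str | Path,
    *,
    stem: str = "evaluation",
) -> dict[str, float]:
    """Write the metric tables and return the headline numbers.

    Produces ``<stem>_metrics.csv`` (per-stage PRE/REC/F1 in percent, in the
    column order W, N1, N2, N3, REM, Accuracy), ``<stem>_confusion.csv``
    (raw counts) and ``<stem>_report.txt`` (human-readable).  Returns
    {"accuracy": ..., "macro_f1": ...} as fractions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics = per_class_metrics(cm)
    acc = accuracy(cm)
    mf1 = macro_f1(cm)

    names = [s.name for s in STAGE_ORDER]
    with open(out_dir / f"{stem}_metrics.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", *names, "Accuracy"])
        for row_name, attr in (("PRE", "precision"), ("REC", "recall"),
                               ("F1", "f1")):
            writer.writerow(
                [row_name]
                + [f"{getattr(metrics[s], attr) * 100:.2f}" for s in STAGE_ORDER]
                + [f"{acc * 100:.2f}"]
            )
        writer.writerow(["MF1", *([""] * len(names)), f"{mf1 * 100:.2f}"])

    with open(out_dir / f"{stem}_confusion.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred", *names])
        for i, s in enumerate(STAGE_ORDER):
            writer.writerow([s.name, *cm.counts[i].tolist()])

    lines = [
        "Sleep-staging evaluation",
        f"  epochs scored : {cm.total}",
        f"  accuracy      : {acc * 100:.2f}%",
        f"  macro F1      : {mf1 * 100:.2f}%",
        "",
        "  stage   PRE%    REC%     F1%",
    ]
    for s in STAGE_ORDER:
        m = metrics[s]
        lines.append(
            f"  {s.name:<5} {m.precision * 100:6.2f}  {m.recall * 100:6.2f}"
            f"  {m.f1 * 100:6.2f}"
        )
    (out_dir / f"{stem}_report.txt").write_text("\n".join(lines) + "\n")
    return {"accuracy": acc, "macro_f1": mf1}
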