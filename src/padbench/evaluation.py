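"""Performance metrics per grid cell and paired comparisons across folds.

Accuracy and per-label F1 are computed from binarized predictions
(threshold 0.5 for the binary task, argmax over the seven softmax outputs
for the enzyme-class task); AUC from the raw probabilities (binary task
only).  Macro F1 is the unweighted mean of per-label F1, insensitive to
class imbalance.  Padding and architecture conditions are compared across
folds with two-sided Wilcoxon signed-rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .benchmark import RunRecord

TASK1_LABELS = (0, 1)
TASK2_LABELS = (1, 2, 3, 4, 5, 6, 7)


@dataclass
class MetricsRecord:
    """Metrics for one (task, architecture, padding, fold) cell."""

    task: int
    architecture: str
    padding: str
    fold: int
    accuracy: float
    per_label_f1: dict[int, float]
    macro_f1: float
    auc: float | None = None            # task 1 only


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    degenerate: bool = False            # all paired differences were zero


def compute_metrics(record: RunRecord, y_true: np.ndarray) -> MetricsRecord:
    """Metrics for one cell, aligned by test-sample order.

    A label absent from the truth has an undefined F1 and is excluded from
    the macro mean with a warning.
    """
    y_true = np.asarray(y_true)
    probs = record.probabilities
    if record.task == 1:
        y_pred = (probs >= 0.5).astype(int)
        labels = TASK1_LABELS
        auc = float(roc_auc_score(y_true, probs)) if len(set(y_true)) == 2 else None
    else:
        y_pred = probs.argmax(axis=1) + 1   # classes are 1..7
        labels = TASK2_LABELS
        auc = None

    acc = float(accuracy_score(y_true, y_pred))
    present = [l for l in labels if (y_true == l).any()]
    absent = [l for l in labels if l not in present]
    if absent:
        warnings.warn(
            f"labels {absent} absent from truth; excluded from macro F1",
            stacklevel=2)
    f1s = f1_score(y_true, y_pred, labels=present, average=None, zero_division=0)
    per_label = {int(l): float(v) for l, v in zip(present, f1s)}
    macro = float(np.mean(list(per_label.values())))
    return MetricsRecord(record.task, record.architecture, record.padding,
                         record.fold, acc, per_label, macro, auc)


def paired_wilcoxon(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on fold-paired metric series.

    Uses the exact null distribution for n <= 25 (when free of zero
    differences and ties) and the normal approximation with continuity
    correction otherwise.  All-zero differences are degenerate: reported
    as p = 1 with a flag.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("need two equal-length paired series of length >= 5")
    d = a - b
    if np.all(d == 0):
        return WilcoxonResult(0.0, 1.0, degenerate=True)
    nonzero = d[d != 0]
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    if len(a) <= 25 and not ties and not np.any(d == 0):
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return WilcoxonResult(float(res.statistic), float(res.pvalue))


def metrics_table(metrics: list[MetricsRecord]) -> pd.DataFrame:
    """Long-format table: one row per (cell, metric, label).

    Per-label F1 rows carry the label; macro F1, accuracy and AUC rows use
    label ``"macro"``, ``"all"`` and ``"all"``.  This is the input to the
    explanatory models.
    """
    rows = []
    for m in metrics:
        base = dict(task=m.task, architecture=m.architecture, padding=m.padding,
                    fold=m.fold)
        for label, v in m.per_label_f1.items():
            rows.append({**base, "metric": "f1", "label": str(label), "value": v})
        rows.append({**base, "metric": "f1", "label": "macro", "value": m.macro_f1})
        rows.append({**base, "metric": "accuracy", "label": "all", "value": m.accuracy})
        if m.auc is not None:
            rows.append({**base, "metric": "auc", "label": "all", "value": m.auc})
    return pd.DataFrame(rows)
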