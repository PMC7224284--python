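"""Classification performance metrics, ROC/PR curves and dispersion.

Point metrics follow the standard confusion-table definitions; the F-score
is the harmonic mean of PPV and sensitivity (F1). Metrics whose denominator
is empty (e.g. PPV with no positive decisions) are reported as None, never
silently zero. ROC curves use a full threshold sweep with trapezoidal AUC;
the precision-recall AUC uses the step-wise average-precision rule, which
is unbiased where PR trapezoids are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve, auc

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "roc_pr_curves",
    "grouped_accuracy_sd",
    "table1_consistency",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float | None
    balanced_accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f_score: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f_score": self.f_score,
        }


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(labels, decisions) -> ConfusionMetrics:
    """Standard binary metrics from labels and hard decisions.

    F-score is the harmonic mean of PPV and sensitivity. Undefined metrics
    (zero denominators) come back as None.
    """
    y = np.asarray(labels).astype(bool)
    d = np.asarray(decisions).astype(bool)
    if y.shape != d.shape:
        raise ValueError("labels and decisions must align")
    tp = int(np.sum(y & d))
    fn = int(np.sum(y & ~d))
    tn = int(np.sum(~y & ~d))
    fp = int(np.sum(~y & d))
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    f = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f = 2.0 * ppv * sens / (ppv + sens)
    bal = (sens + spec) / 2.0 if (sens is not None and spec is not None) else None
    return ConfusionMetrics(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        balanced_accuracy=bal,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f_score=f,
    )


def balanced_accuracy(labels, decisions) -> float:
    m = confusion_metrics(labels, decisions)
    if m.balanced_accuracy is None:
        raise ValueError("balanced accuracy undefined: a class is absent")
    return m.balanced_accuracy


def roc_pr_curves(labels, scores) -> dict:
    """ROC (threshold sweep, trapezoidal AUC) and precision-recall curve
    (average-precision AUC) for one score vector."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, roc_thr = roc_curve(y, s)
    precision, recall, pr_thr = precision_recall_curve(y, s)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "roc_auc": float(auc(fpr, tpr)),
        "precision": precision,
        "recall": recall,
        "pr_thresholds": pr_thr,
        "pr_auc": float(average_precision_score(y, s)),
    }


def grouped_accuracy_sd(table: pd.DataFrame, group: str, label_col: str = "label",
                        decision_col: str = "decision") -> float:
    """Sample SD of per-group accuracies (inter-stack / inter-subject
    consistency). ``group`` names the grouping column."""
    if group not in table.columns:
        raise ValueError(f"unknown grouping column {group!r}")
    accs = []
    for _, g in table.groupby(group):
        accs.append(float((g[label_col].values == g[decision_col].values).mean()))
    if len(accs) < 2:
        raise ValueError("need at least two groups for a dispersion estimate")
    return float(np.std(accs, ddof=1))


def table1_consistency(counts: dict) -> dict:
    """Recompute the patch bookkeeping of a per-class count table.

    ``counts`` maps (diagnosis, cell status) to patch counts, e.g.
    {('healthy', True): 566, ('AD', True): 853, ('healthy', False): 1018,
    ('AD', False): 1226}. Returns row/column totals and the living-cell
    fraction (as a percentage); the fraction is None for an all-zero table.
    """
    vals = np.array(list(counts.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("counts must be non-negative")
    groups = sorted({k[0] for k in counts})
    with_cells = sum(v for (g, c), v in counts.items() if c)
    without_cells = sum(v for (g, c), v in counts.items() if not c)
    total = with_cells + without_cells
    by_group = {g: sum(v for (gg, c), v in counts.items() if gg == g) for g in groups}
    return {
        "with_cells": with_cells,
        "without_cells": without_cells,
        "group_totals": by_group,
        "total": total,
        "living_cell_percent": (100.0 * with_cells / total) if total > 0 else None,
    }
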