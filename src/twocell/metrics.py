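"""Evaluation metrics for predicted vs. true cell-type labels.

Seven summary numbers: overall accuracy, adjusted Rand index, macro-F1,
Cohen's kappa, and the median of the per-class one-vs-rest F1, precision and
recall (each cell type treated as its own binary classification task).
Per-class rows are also reported.

Conventions: undefined precision/recall (no predicted or no true positives
for a class) is set to 0; macro-F1 and the medians average over the classes
present in the *truth*, while classes that are only predicted contribute
zero-F1 rows to the per-class table; medians over an even class count use
midpoint interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    adjusted_rand_score,
    cohen_kappa_score,
    precision_recall_fscore_support,
)

from .io import LabelVector


@dataclass
class MetricReport:
    accuracy: float
    ari: float
    macro_f1: float
    cohen_kappa: float
    median_f1: float
    median_precision: float
    median_recall: float
    per_class: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ari": self.ari,
            "macro_f1": self.macro_f1,
            "cohen_kappa": self.cohen_kappa,
            "median_f1": self.median_f1,
            "median_precision": self.median_precision,
            "median_recall": self.median_recall,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def _labels(x) -> np.ndarray:
    if isinstance(x, LabelVector):
        return x.labels.astype(str)
    return np.asarray(x, dtype=str)


def evaluate(pred, truth) -> MetricReport:
    """Score a predicted labeling against ground truth (same cells, same order)."""
    y_pred = _labels(pred)
    y_true = _labels(truth)
    if len(y_pred) != len(y_true):
        raise ValueError(f"{len(y_pred)} predictions for {len(y_true)} true labels")
    truth_classes = np.unique(y_true)
    all_classes = np.unique(np.concatenate([y_true, y_pred]))

    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=all_classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(all_classes, name="celltype"),
    )
    in_truth = np.isin(all_classes, truth_classes)
    return MetricReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        ari=float(adjusted_rand_score(y_true, y_pred)),
        macro_f1=float(f1[in_truth].mean()),
        cohen_kappa=float(cohen_kappa_score(y_true, y_pred)),
        median_f1=float(np.median(f1[in_truth])),
        median_precision=float(np.median(prec[in_truth])),
        median_recall=float(np.median(rec[in_truth])),
        per_class=per_class,
    )
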