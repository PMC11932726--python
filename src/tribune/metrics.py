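"""Agreement metrics between predicted and reference cell-type labels.

Covers the standard clustering/classification panel — Rand index, accuracy,
weighted F1, Cohen's kappa, Matthews correlation coefficient — plus Pielou's
evenness of a label composition.  The heavy lifting is delegated to
scikit-learn; "other"/"undefined" predictions are ordinary classes unless
``ignore_ambiguous`` is set, in which case those cells are dropped first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .data_model import OTHER_LABEL, UNDEFINED_LABEL


@dataclass
class MetricsReport:
    rand_index: float
    adjusted_rand_index: float
    accuracy: float
    weighted_f1: float
    cohens_kappa: float
    mcc: float
    per_class: pd.DataFrame  # precision / recall / f1 / support per class

    def to_dict(self) -> dict:
        return {
            "rand_index": self.rand_index,
            "adjusted_rand_index": self.adjusted_rand_index,
            "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "cohens_kappa": self.cohens_kappa,
            "mcc": self.mcc,
        }


def evaluate(pred, truth, ignore_ambiguous: bool = False) -> MetricsReport:
    """Score predicted labels against ground truth.

    Rand index is the plain (unadjusted) pair-counting index; the adjusted
    variant is reported separately.  Weighted F1 averages per-class F1 by
    true-class support.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(truth)} truths")
    if len(pred) == 0:
        raise ValueError("empty label lists")
    if ignore_ambiguous:
        keep = ~np.isin(pred, (OTHER_LABEL, UNDEFINED_LABEL))
        if not keep.any():
            raise ValueError("all predictions are ambiguous; nothing to evaluate")
        pred, truth = pred[keep], truth[keep]

    pred_s = pred.astype(str)
    truth_s = truth.astype(str)
    classes = sorted(set(truth_s) | set(pred_s))
    prec, rec, f1, support = _skm.precision_recall_fscore_support(
        truth_s, pred_s, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(classes, name="class"),
    )
    return MetricsReport(
        rand_index=float(_skm.rand_score(truth_s, pred_s)),
        adjusted_rand_index=float(_skm.adjusted_rand_score(truth_s, pred_s)),
        accuracy=float(_skm.accuracy_score(truth_s, pred_s)),
        weighted_f1=float(_skm.f1_score(truth_s, pred_s, average="weighted",
                                        zero_division=0)),
        cohens_kappa=float(_skm.cohen_kappa_score(truth_s, pred_s)),
        mcc=float(_skm.matthews_corrcoef(truth_s, pred_s)),
        per_class=per_class,
    )


def pielou_evenness(labels) -> float:
    """Shannon entropy of the label proportions normalized by ln(S).

    S is the number of observed classes; a single-class composition is
    defined as 0.  Natural logarithms throughout.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty label list")
    _, counts = np.unique(labels.astype(str), return_counts=True)
    if len(counts) == 1:
        return 0.0
    p = counts / counts.sum()
    shannon = -np.sum(p * np.log(p))
    return float(shannon / np.log(len(counts)))
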