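"""The nine-metric classification report: accuracy, recall, F1, precision,
R^2 on integer-coded labels, MCC, Cohen's kappa, Hamming loss and Jaccard.

Per-class metrics are averaged per the configured mode (macro by default;
the report records the mode).  R^2 on class labels is statistically odd but
is part of the report's contract; it is computed literally on the integer
codes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass
class ClassificationReport:
    accuracy: float
    recall: float
    f1: float
    precision: float
    r2: float
    mcc: float
    cohen_kappa: float
    hamming_loss: float
    jaccard: float
    averaging: str = "macro"
    n_classes: int = 2

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "recall": self.recall, "f1": self.f1,
            "precision": self.precision, "r2": self.r2, "mcc": self.mcc,
            "cohen_kappa": self.cohen_kappa, "hamming_loss": self.hamming_loss,
            "jaccard": self.jaccard, "averaging": self.averaging,
            "n_classes": self.n_classes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def classification_report(y_true, y_pred, averaging: str = "macro") -> ClassificationReport:
    """Compute the full report from label vectors of equal length.

    ``averaging`` is one of macro / micro / weighted and applies to the
    per-class metrics (precision, recall, F1, Jaccard).  Degenerate cases:
    a single observed class makes kappa (and MCC) 0 with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    if averaging not in ("macro", "micro", "weighted"):
        raise ValueError("averaging must be macro, micro or weighted")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    accuracy = float(_skm.accuracy_score(y_true, y_pred))
    recall = float(_skm.recall_score(y_true, y_pred, labels=labels,
                                     average=averaging, zero_division=0))
    precision = float(_skm.precision_score(y_true, y_pred, labels=labels,
                                           average=averaging, zero_division=0))
    f1 = float(_skm.f1_score(y_true, y_pred, labels=labels,
                             average=averaging, zero_division=0))
    jaccard = float(_skm.jaccard_score(y_true, y_pred, labels=labels,
                                       average=averaging, zero_division=0))
    hamming = float(np.mean(y_true != y_pred))
    if len(np.unique(y_true)) < 2 and len(np.unique(y_pred)) < 2:
        warnings.warn("single observed class: kappa and MCC defined as 0",
                      UserWarning)
        kappa = 0.0
        mcc = 0.0
    else:
        kappa = float(_skm.cohen_kappa_score(y_true, y_pred))
        mcc = float(_skm.matthews_corrcoef(y_true, y_pred))
    if np.var(y_true.astype(float)) == 0:
        warnings.warn("constant y_true: R^2 defined as 1 for perfect "
                      "prediction, else 0", UserWarning)
        r2 = 1.0 if accuracy == 1.0 else 0.0
    else:
        r2 = float(_skm.r2_score(y_true.astype(float), y_pred.astype(float)))
    return ClassificationReport(
        accuracy=accuracy, recall=recall, f1=f1, precision=precision, r2=r2,
        mcc=mcc, cohen_kappa=kappa, hamming_loss=hamming, jaccard=jaccard,
        averaging=averaging, n_classes=int(len(labels)))
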