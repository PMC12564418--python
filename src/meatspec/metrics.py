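"""Confusion-count bookkeeping shared by every classifier in the pipeline.

Class 1 is always the positive (target-origin) class.  Metrics that are
undefined on a given evaluation set (e.g. selectivity with no positives
present) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "rmse"]


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    scheme: str = "train"
    extras: dict = field(default_factory=dict)  # rmse, auc, entropy, ...

    @classmethod
    def from_predictions(cls, y_true, y_pred, scheme: str = "train") -> "MetricsReport":
        yt = np.asarray(y_true, dtype=int).ravel()
        yp = np.asarray(y_pred, dtype=int).ravel()
        if yt.size != yp.size:
            raise ValueError("y_true and y_pred lengths differ")
        if yt.size == 0:
            raise ValueError("empty evaluation set")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            scheme=scheme,
        )

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan

    @property
    def selectivity(self) -> float:
        """Sensitivity/recall on the positive class (the field calls it selectivity)."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    recall = selectivity

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or (p + r) == 0:
            return math.nan
        return 2 * p * r / (p + r)

    @property
    def misclassification_pct(self) -> float:
        return 100.0 * (1.0 - self.accuracy)

    def as_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "selectivity": self.selectivity,
            "precision": self.precision,
            "f1": self.f1,
            "misclassification_pct": self.misclassification_pct,
        }
        d.update(self.extras)
        return d


def rmse(y_true, y_pred) -> float:
    """Root mean squared error, sqrt(mean((y - yhat)^2))."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size == 0 or yt.size != yp.size:
        raise ValueError("rmse needs equal-length non-empty vectors")
    return float(np.sqrt(np.mean((yt - yp) ** 2)))
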