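"""Training, leave-one-out, and Venetian-blind validation schemes.

Every classifier family is evaluated the same three ways: resubstitution on
the calibration rows, leave-one-out (the model — including any stateful
preprocessing — is refit with each sample held out), and the structured
"Venetian blind" hold-out where every third sample (1-based positions
3, 6, 9, ...) is withheld as a pseudo-external set, i.e. 33% out, 67% in.

Model families plug in as factories: ``factory(train: SpectraSet) -> model``
where the model has a ``predict(SpectraSet) -> labels`` callable, so any
fold-local preprocessing lives inside the factory and never sees held-out
rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import SpectraSet
from .metrics import MetricsReport

__all__ = ["SplitScheme", "venetian_split", "training_accuracy",
           "loo_accuracy", "excluded_accuracy"]

ModelFactory = Callable[[SpectraSet], object]


@dataclass(frozen=True)
class SplitScheme:
    kind: str = "venetian"            # train_only | loo | venetian
    stride: int = 3
    offset: int = 2                   # 0-based; 2 -> 1-based positions 3, 6, 9...

    def __post_init__(self) -> None:
        if self.kind not in ("train_only", "loo", "venetian"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.stride < 2:
            raise ValueError("stride must be >= 2")
        if not 0 <= self.offset < self.stride:
            raise ValueError("offset must satisfy 0 <= offset < stride")


def venetian_split(n: int, stride: int = 3, offset: int = 2):
    """Deterministic systematic split: excluded = {i : i mod stride == offset}."""
    if stride < 2:
        raise ValueError("stride must be >= 2")
    if not 0 <= offset < stride:
        raise ValueError("offset must satisfy 0 <= offset < stride")
    if n < stride:
        raise ValueError(f"need at least {stride} samples, got {n}")
    idx = np.arange(n)
    excluded = idx[idx % stride == offset]
    train = idx[idx % stride != offset]
    return train, excluded


def _predict(model, data: SpectraSet) -> np.ndarray:
    out = model.predict(data)
    if isinstance(out, tuple):  # (labels, scores/distances)
        out = out[0]
    return np.asarray(out, dtype=int).ravel()


def training_accuracy(model, data: SpectraSet) -> float:
    """Resubstitution accuracy, in percent."""
    if data.n == 0:
        raise ValueError("empty dataset")
    pred = _predict(model, data)
    return 100.0 * float(np.mean(pred == data.label))


def loo_accuracy(model_factory: ModelFactory, data: SpectraSet):
    """Leave-one-out accuracy (percent) with full refits, plus per-sample predictions."""
    n = data.n
    if n < 3:
        raise ValueError("need at least 3 samples for LOO")
    preds = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.flatnonzero(np.arange(n) != i)
        try:
            model = model_factory(data.rows(keep))
        except Exception as e:
            raise RuntimeError(f"model factory failed on LOO fold {i}: {e}") from e
        preds[i] = _predict(model, data.rows([i]))[0]
    acc = 100.0 * float(np.mean(preds == data.label))
    return acc, preds


def excluded_accuracy(model_factory: ModelFactory, data: SpectraSet,
                      scheme: SplitScheme | None = None):
    """Fit on the Venetian-blind training part, score the excluded part.

    Returns ``(accuracy_percent, MetricsReport)``.
    """
    scheme = scheme or SplitScheme()
    if scheme.kind != "venetian":
        raise ValueError("excluded_accuracy expects a venetian scheme")
    tr, ex = venetian_split(data.n, scheme.stride, scheme.offset)
    model = model_factory(data.rows(tr))
    test = data.rows(ex)
    preds = _predict(model, test)
    report = MetricsReport.from_predictions(test.label, preds, scheme="excluded")
    return 100.0 * float(np.mean(preds == test.label)), report
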