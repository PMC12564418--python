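"""Soft Independent Modeling of Class Analogy for two-class origin screening.

One PCA model is fit per class on that class's training rows alone; an
unknown spectrum is assigned to the class whose model reconstructs it best,
i.e. the class with the smallest residual distance d_k = sqrt(Q_k).  Coomans
coordinates (d_0, d_1) visualize membership, with empirical per-class
critical distances at the 95th percentile of the training distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpectraSet
from .metrics import MetricsReport
from .pca import PCAModel, auto_components, fit_pca, q_residual

__all__ = ["SIMCAModel", "fit_simca", "classify", "evaluate_simca",
           "coomans_coordinates"]

CLASSES = (0, 1)


@dataclass
class SIMCAModel:
    class_models: dict[int, PCAModel]
    class_components: dict[int, int]

    def distances(self, x: np.ndarray) -> np.ndarray:
        """Residual distance of each row to each class model, shape (n, 2)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        cols = [np.sqrt(np.atleast_1d(q_residual(self.class_models[k], x)))
                for k in CLASSES]
        return np.column_stack(cols)


def fit_simca(
    train: SpectraSet,
    components_per_class: dict[int, int] | None = None,
    variance_target: float = 0.90,
    cap: int = 10,
) -> SIMCAModel:
    """Independent PCA per class; components auto-chosen at ≥90% class variance."""
    models, comps = {}, {}
    for k in CLASSES:
        idx = np.flatnonzero(train.label == k)
        if idx.size < 3:
            raise ValueError(f"class {k} has {idx.size} training rows; need >= 3")
        sub = train.rows(idx)
        if components_per_class and k in components_per_class:
            a = components_per_class[k]
        else:
            a = auto_components(sub, target=variance_target, cap=cap)
        models[k] = fit_pca(sub, a)
        comps[k] = a
    return SIMCAModel(class_models=models, class_components=comps)


def classify(m: SIMCAModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign to the class with the smallest residual distance.

    Ties go to class 0 (with a warning).  Returns ``(labels, distances)``.
    """
    d = m.distances(x)
    ties = d[:, 0] == d[:, 1]
    if ties.any():
        warnings.warn(f"{int(ties.sum())} tie(s) in SIMCA distances; assigned to class 0")
    labels = (d[:, 1] < d[:, 0]).astype(int)
    return labels, d


def evaluate_simca(m: SIMCAModel, data: SpectraSet, scheme: str = "train") -> MetricsReport:
    labels, _ = classify(m, data.absorbance)
    return MetricsReport.from_predictions(data.label, labels, scheme=scheme)


@dataclass
class CoomansPoint:
    sample_id: str
    d_class0: float
    d_class1: float
    true_label: int
    predicted_label: int


def coomans_coordinates(
    m: SIMCAModel, data: SpectraSet, train: SpectraSet | None = None,
    percentile: float = 95.0,
) -> tuple[list[CoomansPoint], dict[int, float]]:
    """Per-sample (d0, d1) pairs plus per-class critical distances.

    The critical distance of class k is the ``percentile`` of that class's
    *training* rows' distances to its own model; pass ``train`` to compute it
    on the calibration set, else ``data`` is used.
    """
    labels, d = classify(m, data.absorbance)
    points = [
        CoomansPoint(str(sid), float(d0), float(d1), int(t), int(p))
        for sid, d0, d1, t, p in zip(data.sample_id, d[:, 0], d[:, 1], data.label, labels)
    ]
    ref = train if train is not None else data
    crit = {}
    ref_d = m.distances(ref.absorbance)
    for k in CLASSES:
        own = ref_d[ref.label == k, k]
        crit[k] = float(np.percentile(own, percentile)) if own.size else float("nan")
    return points, crit
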