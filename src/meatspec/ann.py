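"""Feed-forward MLP classification with architecture search and ROI mapping.

Candidates span five hidden-layer layouts — (50), (100), (50, 20),
(100, 50), (50, 30, 10) — crossed with iteration caps 1000/2000/3000, all
ReLU + Adam with early stopping on a held-out validation split.  The
candidate with the best validation score wins; ties resolve to the smaller
network, then the smaller cap.  Features are z-scored with training
statistics before training.

Region-of-importance (ROI) mapping attributes the trained classifier's
decisions to wavenumber intervals by jointly permuting sliding blocks of
contiguous columns and recording the mean rise in log-loss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.neural_network import MLPClassifier

from .io import SpectraSet
from .metrics import MetricsReport

__all__ = ["ANNConfig", "ANNModel", "ROIMap", "fit_ann", "evaluate_ann",
           "roi_mapping"]

PROB_CLIP = 1e-12


@dataclass
class ANNConfig:
    hidden_layouts: tuple = ((50,), (100,), (50, 20), (100, 50), (50, 30, 10))
    max_iters: tuple = (1000, 2000, 3000)
    validation_fraction: float = 0.1
    seed: int = 0


@dataclass
class ANNModel:
    classifier: MLPClassifier
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    wavenumbers: np.ndarray
    layout: tuple
    max_iter: int
    validation_loss: float
    converged: bool
    training_report: MetricsReport = None
    selection_table: list = field(default_factory=list)

    def _features(self, data: SpectraSet) -> np.ndarray:
        if data.p != self.wavenumbers.size or not np.allclose(
            data.wavenumbers, self.wavenumbers
        ):
            raise ValueError("wavenumber axis differs from the training axis")
        return (data.absorbance - self.scaler_mean) / self.scaler_sd

    def predict(self, data: SpectraSet) -> np.ndarray:
        return self.classifier.predict(self._features(data)).astype(int)

    def predict_proba(self, data: SpectraSet) -> np.ndarray:
        return self.classifier.predict_proba(self._features(data))


_PATIENCE = 15       # epochs without validation-loss improvement before stop
_LOSS_TOL = 1e-4     # minimum improvement that resets the patience counter
_LOSS_FLOOR = 1e-3   # validation loss at which nothing is left to learn


def _train_mlp(z: np.ndarray, y: np.ndarray, layout: tuple, cap: int,
               val_fraction: float, seed: int):
    """One candidate: Adam minibatch epochs, early stopping on validation loss.

    The weights from the best-validation-loss epoch are restored at the end.
    Returns ``(classifier, best_val_loss, epochs_run, converged)``.
    """
    from sklearn.model_selection import train_test_split

    idx_tr, idx_val = train_test_split(
        np.arange(len(y)), test_size=val_fraction, random_state=seed,
        stratify=y if np.unique(y).size > 1 else None,
    )
    z_tr, y_tr = z[idx_tr], y[idx_tr]
    z_val, y_val = z[idx_val], y[idx_val]
    batch = min(32, len(y_tr))
    clf = MLPClassifier(
        hidden_layer_sizes=layout, activation="relu", solver="adam",
        learning_rate_init=0.01, batch_size=batch, random_state=seed,
        max_iter=1, warm_start=False,
    )
    rng = np.random.default_rng(seed)
    classes = np.array([0, 1])
    best_loss, best_state, best_epoch = np.inf, None, 0
    epoch = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        while epoch < cap:
            order = rng.permutation(len(y_tr))
            for start in range(0, len(order), batch):
                part = order[start:start + batch]
                clf.partial_fit(z_tr[part], y_tr[part], classes=classes)
            epoch += 1
            proba = clf.predict_proba(z_val)
            p1 = np.clip(proba[:, 1], PROB_CLIP, 1 - PROB_CLIP)
            val_loss = float(log_loss(
                y_val, np.column_stack([1 - p1, p1]), labels=[0, 1]))
            # demand a materially better loss (10% relative, 1e-4 absolute);
            # oscillation around a plateau must not reset the patience clock
            if best_state is None or val_loss < best_loss - max(
                    _LOSS_TOL, 0.10 * best_loss):
                best_loss = val_loss
                best_epoch = epoch
                best_state = ([c.copy() for c in clf.coefs_],
                              [b.copy() for b in clf.intercepts_])
                if best_loss < _LOSS_FLOOR:
                    break
            elif epoch - best_epoch >= _PATIENCE:
                break
    if best_state is not None:
        clf.coefs_, clf.intercepts_ = best_state
    return clf, best_loss, epoch, epoch < cap


def fit_ann(train: SpectraSet, cfg: ANNConfig | None = None) -> ANNModel:
    """Train every (layout, cap) candidate, keep the best by validation loss.

    Ties resolve to the smaller network (fewer units, then fewer layers),
    then the smaller iteration cap.
    """
    cfg = cfg or ANNConfig()
    if train.n < 20:
        raise ValueError("need at least 20 training samples")
    x = train.absorbance
    sd = x.std(axis=0, ddof=1)
    scaler_mean, scaler_sd = x.mean(axis=0), np.maximum(sd, 1e-12)
    z = (x - scaler_mean) / scaler_sd
    y = train.label

    best = None
    table = []
    for layout in cfg.hidden_layouts:
        prev = None
        for cap in sorted(cfg.max_iters):
            if prev is not None and prev[2] < cap:
                # early stopping already fired below this cap; a longer cap
                # reproduces the same training trajectory exactly
                clf, val_loss, epochs, converged = prev[0], prev[1], prev[2], True
            else:
                clf, val_loss, epochs, converged = _train_mlp(
                    z, y, layout, cap, cfg.validation_fraction, cfg.seed)
                if converged:
                    prev = (clf, val_loss, epochs)
            table.append({"layout": layout, "max_iter": cap,
                          "val_loss": val_loss, "epochs": epochs,
                          "converged": converged})
            cand = (val_loss, (sum(layout), len(layout), cap))
            if best is None or cand < best[0]:
                best = (cand, clf, layout, cap, val_loss, converged)

    _, clf, layout, cap, val_loss, converged = best
    if not any(row["converged"] for row in table):
        warnings.warn("no ANN candidate converged within its iteration cap")
    model = ANNModel(
        classifier=clf, scaler_mean=scaler_mean, scaler_sd=scaler_sd,
        wavenumbers=train.wavenumbers.copy(), layout=layout, max_iter=cap,
        validation_loss=val_loss, converged=converged, selection_table=table,
    )
    model.training_report = evaluate_ann(model, train, scheme="train")
    return model


def evaluate_ann(model: ANNModel, data: SpectraSet, scheme: str = "eval") -> MetricsReport:
    """Confusion counts plus cross-entropy and AUC (positive class = 1)."""
    proba = model.predict_proba(data)
    classes = list(model.classifier.classes_)
    p1 = proba[:, classes.index(1)] if 1 in classes else np.zeros(data.n)
    labels = model.predict(data)
    report = MetricsReport.from_predictions(data.label, labels, scheme=scheme)
    p_clip = np.clip(p1, PROB_CLIP, 1 - PROB_CLIP)
    report.extras["cross_entropy"] = float(
        log_loss(data.label, np.column_stack([1 - p_clip, p_clip]), labels=[0, 1])
    )
    if np.unique(data.label).size < 2:
        report.extras["auc"] = math.nan
    else:
        report.extras["auc"] = float(roc_auc_score(data.label, p1))
    return report


@dataclass
class ROIMap:
    wavenumbers: np.ndarray
    raw_drop: np.ndarray     # mean log-loss increase per window centre
    normalized: np.ndarray   # negatives floored at 0, scaled to max 1
    window: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "wavenumber": self.wavenumbers,
            "raw_drop": self.raw_drop,
            "normalized": self.normalized,
        })


def roi_mapping(model: ANNModel, data: SpectraSet, window: int = 11,
                repeats: int = 5, seed: int = 0) -> ROIMap:
    """Sliding-block permutation importance on the log-loss scale.

    For each window centre the block of ``window`` contiguous columns is
    jointly row-permuted (``repeats`` times) and the mean increase in binary
    log-loss is assigned to the centre.
    """
    p = data.p
    if window > p:
        raise ValueError("window exceeds the number of wavenumber columns")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    rng = np.random.default_rng(seed)
    z = model._features(data)
    classes = list(model.classifier.classes_)
    idx1 = classes.index(1) if 1 in classes else None

    def loss_of(features: np.ndarray) -> float:
        proba = model.classifier.predict_proba(features)
        p1 = proba[:, idx1] if idx1 is not None else np.zeros(len(features))
        p_clip = np.clip(p1, PROB_CLIP, 1 - PROB_CLIP)
        return float(log_loss(data.label, np.column_stack([1 - p_clip, p_clip]),
                              labels=[0, 1]))

    base = loss_of(z)
    half = window // 2
    raw = np.zeros(p)
    for center in range(p):
        lo, hi = max(0, center - half), min(p, center + half + 1)
        drops = []
        for _ in range(repeats):
            perm = rng.permutation(len(z))
            zp = z.copy()
            zp[:, lo:hi] = z[perm][:, lo:hi]
            drops.append(loss_of(zp) - base)
        raw[center] = float(np.mean(drops))
    clipped = np.clip(raw, 0.0, None)
    peak = clipped.max()
    normalized = clipped / peak if peak > 0 else clipped
    return ROIMap(wavenumbers=data.wavenumbers.copy(), raw_drop=raw,
                  normalized=normalized, window=window)
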