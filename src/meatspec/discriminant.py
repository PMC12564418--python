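"""PCA-LDA and PLS-LDA hybrid classifiers.

Both workflows z-score every wavenumber column (training statistics only),
reduce to at most 10 components — unsupervised PCA scores or supervised PLS
latent-variable scores against the 0/1 origin label — and run a two-class
pooled-covariance linear discriminant on the reduced features.  With two
classes the discriminant has exactly one canonical axis; score plots pair
LD1 with the first reducer component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .io import SpectraSet
from .metrics import MetricsReport
from .pca import fit_pca

__all__ = ["DiscriminantModel", "fit_pca_lda", "fit_pls_lda", "predict"]

SD_FLOOR = 1e-12


@dataclass
class _Scaler:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "_Scaler":
        sd = x.std(axis=0, ddof=1)
        return cls(mean=x.mean(axis=0), sd=np.maximum(sd, SD_FLOOR))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class _LDA:
    """Two-class linear discriminant with pooled within-class covariance."""

    direction: np.ndarray   # Sw^-1 (mu1 - mu0)
    threshold: float        # decision value on w.x
    mu0: np.ndarray
    mu1: np.ndarray
    log_prior_ratio: float

    @classmethod
    def fit(cls, scores: np.ndarray, y: np.ndarray) -> "_LDA":
        y = np.asarray(y, dtype=int)
        x0, x1 = scores[y == 0], scores[y == 1]
        if len(x0) < 2 or len(x1) < 2:
            raise ValueError("each class needs >= 2 rows for LDA")
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        n0, n1 = len(x0), len(x1)
        sw = ((x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)) / (n0 + n1 - 2)
        sw = np.atleast_2d(sw)
        try:
            direction = np.linalg.solve(sw, mu1 - mu0)
            if not np.all(np.isfinite(direction)):
                raise np.linalg.LinAlgError("non-finite solve")
        except np.linalg.LinAlgError:
            warnings.warn("singular within-class covariance; ridge-regularizing")
            ridge = 1e-8 * np.trace(sw) / sw.shape[0]
            direction = np.linalg.solve(sw + ridge * np.eye(sw.shape[0]), mu1 - mu0)
        log_prior = float(np.log(n1 / n0))
        thr = float(direction @ (mu0 + mu1) / 2.0) - log_prior
        return cls(direction=direction, threshold=thr, mu0=mu0, mu1=mu1,
                   log_prior_ratio=log_prior)

    def decision(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.direction - self.threshold

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return (self.decision(scores) > 0).astype(int)


@dataclass
class DiscriminantModel:
    kind: str                  # "pca_lda" | "pls_lda"
    wavenumbers: np.ndarray
    scaler: _Scaler
    reducer: object            # PCAModel or fitted PLSRegression
    lda: _LDA
    n_components: int
    training_report: MetricsReport

    def _reduce(self, x: np.ndarray) -> np.ndarray:
        z = self.scaler.apply(x)
        if self.kind == "pca_lda":
            return self.reducer.transform(z)
        return self.reducer.transform(z)  # PLSRegression.transform -> X-scores


def _check_axis(model: DiscriminantModel, data: SpectraSet) -> None:
    if data.p != model.wavenumbers.size or not np.allclose(
        data.wavenumbers, model.wavenumbers
    ):
        raise ValueError("wavenumber axis differs from the training axis")


def _finish(kind, train, scaler, reducer, scores, n_comp) -> DiscriminantModel:
    lda = _LDA.fit(scores, train.label)
    model = DiscriminantModel(
        kind=kind, wavenumbers=train.wavenumbers.copy(), scaler=scaler,
        reducer=reducer, lda=lda, n_components=n_comp,
        training_report=MetricsReport.from_predictions(
            train.label, lda.predict(scores)
        ),
    )
    return model


def _resolve_components(n_components, train) -> int:
    cap = min(10, train.n - 2, train.p)
    a = cap if n_components is None else min(n_components, cap)
    if a < 1:
        raise ValueError("not enough samples for any component")
    return a


def fit_pca_lda(train: SpectraSet, n_components: int | None = None) -> DiscriminantModel:
    """z-score -> PCA scores (<=10) -> two-class LDA."""
    a = _resolve_components(n_components, train)
    scaler = _Scaler.fit(train.absorbance)
    z = scaler.apply(train.absorbance)
    reducer = fit_pca(train.with_absorbance(z), a)
    return _finish("pca_lda", train, scaler, reducer, reducer.scores, a)


def fit_pls_lda(train: SpectraSet, n_components: int | None = None) -> DiscriminantModel:
    """z-score -> PLS X-scores against the 0/1 label (<=10) -> two-class LDA."""
    a = _resolve_components(n_components, train)
    scaler = _Scaler.fit(train.absorbance)
    z = scaler.apply(train.absorbance)
    reducer = PLSRegression(n_components=a, scale=False)
    reducer.fit(z, train.label.astype(float))
    scores = reducer.transform(z)
    return _finish("pls_lda", train, scaler, reducer, scores, a)


def predict(model: DiscriminantModel, data: SpectraSet) -> tuple[np.ndarray, np.ndarray]:
    """Labels and canonical coordinates (LD1, first reducer score)."""
    _check_axis(model, data)
    scores = model._reduce(data.absorbance)
    labels = model.lda.predict(scores)
    canonical = np.column_stack([model.lda.decision(scores), scores[:, 0]])
    return labels, canonical
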