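"""PCA decomposition with Hotelling T², Q residuals and empirical outlier flagging.

The decomposition is the usual X = T Pᵀ + E on mean-centred data, computed
by SVD with a deterministic sign convention (the largest-magnitude loading
element of each component is positive).  Sample leverage inside the model is
Hotelling's T² = tᵀ Sₜ⁻¹ t with Sₜ the training-score covariance; lack of
fit is the Q residual, the squared norm of the reconstruction error.
Outliers are flagged by the empirical rule: either statistic above its
training mean + 3 standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpectraSet

__all__ = ["PCAModel", "OutlierReport", "fit_pca", "hotelling_t2", "q_residual",
           "flag_outliers", "auto_components"]


@dataclass
class PCAModel:
    mean: np.ndarray                # (p,) column means
    loadings: np.ndarray            # (p, A), orthonormal columns
    scores: np.ndarray              # (n, A) training scores
    explained_variance: np.ndarray  # fraction per retained component
    all_explained: np.ndarray       # fraction for every non-trivial component
    n_components: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project (rows of) x into the score space."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.mean.size:
            raise ValueError(
                f"expected {self.mean.size} columns, got {x.shape[1]}"
            )
        return (x - self.mean) @ self.loadings

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.transform(x) @ self.loadings.T + self.mean


@dataclass
class OutlierReport:
    sample_id: np.ndarray
    t2: np.ndarray
    q: np.ndarray
    t2_threshold: float
    q_threshold: float
    flagged: np.ndarray  # bool per sample

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "sample_id": self.sample_id,
            "t2": self.t2,
            "q": self.q,
            "flagged": self.flagged,
        })


def fit_pca(s: SpectraSet, n_components: int) -> PCAModel:
    """Mean-centred SVD PCA retaining ``n_components`` components."""
    x = s.absorbance
    n, p = x.shape
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}], got {n_components}")
    mean = x.mean(axis=0)
    xc = x - mean
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| element positive per component
    v = vt.T
    for a in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, a])))
        if v[j, a] < 0:
            v[:, a] = -v[:, a]
            u[:, a] = -u[:, a]
    total = float(np.sum(sv**2))
    all_frac = (sv[:max_a] ** 2 / total) if total > 0 else np.zeros(max_a)
    loadings = v[:, :n_components]
    scores = u[:, :n_components] * sv[:n_components]
    return PCAModel(
        mean=mean,
        loadings=loadings,
        scores=scores,
        explained_variance=all_frac[:n_components],
        all_explained=all_frac,
        n_components=n_components,
    )


def auto_components(s: SpectraSet, target: float = 0.95, cap: int = 10) -> int:
    """Smallest A whose cumulative explained variance reaches ``target``."""
    max_a = min(s.n - 1, s.p)
    probe = fit_pca(s, max_a)
    cum = np.cumsum(probe.all_explained)
    reached = np.flatnonzero(cum >= target - 1e-12)
    a = int(reached[0]) + 1 if reached.size else max_a
    return max(1, min(a, cap, max_a))


def hotelling_t2(m: PCAModel, x: np.ndarray) -> np.ndarray:
    """Leverage of sample(s) in score space: tᵀ Sₜ⁻¹ t."""
    t = np.atleast_2d(x)
    if t.shape[1] == m.mean.size:          # raw spectra: project first
        t = m.transform(t)
    elif t.shape[1] != m.n_components:
        raise ValueError("input is neither spectra nor score rows")
    st = np.cov(m.scores, rowvar=False, ddof=1)
    st = np.atleast_2d(st)
    try:
        st_inv = np.linalg.inv(st)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "training score covariance is singular; refit with fewer components"
        ) from e
    vals = np.einsum("ij,jk,ik->i", t, st_inv, t)
    return vals if vals.size > 1 else float(vals[0])


def q_residual(m: PCAModel, x: np.ndarray) -> np.ndarray:
    """Squared reconstruction residual ‖(I - PPᵀ)(x - mean)‖²."""
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    xc = x2 - m.mean
    resid = xc - (xc @ m.loadings) @ m.loadings.T
    vals = np.sum(resid**2, axis=1)
    return vals if vals.size > 1 else float(vals[0])


def _empirical_threshold(stat: np.ndarray) -> float:
    return float(stat.mean() + 3.0 * stat.std(ddof=1))


def flag_outliers(s: SpectraSet, n_components: int | None = None) -> tuple[OutlierReport, SpectraSet]:
    """Fit PCA, flag samples with T² or Q above mean + 3 sd, return the report
    and the dataset with flagged rows dropped."""
    if s.n < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    if n_components is None:
        n_components = auto_components(s)
    m = fit_pca(s, n_components)
    t2 = np.atleast_1d(hotelling_t2(m, s.absorbance))
    q = np.atleast_1d(q_residual(m, s.absorbance))
    thr_t2 = _empirical_threshold(t2)
    thr_q = _empirical_threshold(q)
    flagged = (t2 > thr_t2) | (q > thr_q)
    if flagged.all():
        raise ValueError("every sample flagged as outlier; data degenerate")
    report = OutlierReport(
        sample_id=s.sample_id.copy(),
        t2=t2, q=q, t2_threshold=thr_t2, q_threshold=thr_q, flagged=flagged,
    )
    return report, s.rows(~flagged)
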