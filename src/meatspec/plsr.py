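"""PLS1 regression on the 0/1 origin response, with VIP scores.

The response is the class code (1 = target origin, 0 = other) treated as a
continuous variable.  Latent variables are extracted by NIPALS on
mean-centred data; the LV count is chosen by minimizing leave-one-out RMSE
over a candidate list.  Variable Importance in Projection follows the
standard Wold formulation,

    VIP_j = sqrt( p * sum_a (w_ja / ||w_a||)^2 s_a / sum_a s_a ),

with s_a the amount of y-variance explained by LV a, so that the mean
squared VIP is exactly 1 and "VIP > 1" marks above-average contributors.
Classification uses the coding-consistent 0.5 cut: predictions strictly
above 0.5 go to the class coded 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpectraSet
from .metrics import rmse

__all__ = ["PLSRModel", "LVSelection", "fit_plsr", "nipals_pls1",
           "vip_scores", "predict", "predict_and_classify"]


@dataclass
class PLSRModel:
    weights: np.ndarray    # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    beta: np.ndarray       # (p,) coefficients on centred x
    x_mean: np.ndarray
    y_mean: float
    n_components: int
    s_a: np.ndarray        # y-variance explained per LV
    vip: np.ndarray        # (p,)
    wavenumbers: np.ndarray


@dataclass
class LVSelection:
    candidates: np.ndarray
    rmse_loo: np.ndarray
    chosen: int


def nipals_pls1(x: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1 on mean-centred copies of x, y.

    Returns ``(W, P, q, s_a, x_mean, y_mean, A)``; A may be smaller than
    requested when the X residual is exhausted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if y.size != n:
        raise ValueError("y length mismatch")
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}]")
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xr = x - x_mean
    yr = y - y_mean
    ws, ps, qs, svars = [], [], [], []
    for _ in range(n_components):
        cov = xr.T @ yr
        nrm = np.linalg.norm(cov)
        if nrm < 1e-14 or float(np.sum(xr * xr)) < 1e-14:
            warnings.warn(
                f"X residual exhausted after {len(ws)} latent variable(s)",
                stacklevel=2,
            )
            break
        w = cov / nrm
        t = xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            warnings.warn(
                f"X residual exhausted after {len(ws)} latent variable(s)",
                stacklevel=2,
            )
            break
        p_load = xr.T @ t / tt
        q = float(yr @ t / tt)
        xr = xr - np.outer(t, p_load)
        yr = yr - q * t
        ws.append(w)
        ps.append(p_load)
        qs.append(q)
        svars.append(q * q * tt)
    if not ws:
        raise ValueError("no latent variable could be extracted (X or cov degenerate)")
    return (np.column_stack(ws), np.column_stack(ps), np.array(qs),
            np.array(svars), x_mean, y_mean, len(ws))


def _beta_from(w: np.ndarray, p_load: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression vector at LV count a: W_a (P_a' W_a)^-1 q_a."""
    wa, pa, qa = w[:, :a], p_load[:, :a], q[:a]
    return wa @ np.linalg.solve(pa.T @ wa, qa)


def fit_plsr(
    train: SpectraSet,
    max_lv: int = 15,
    candidates: np.ndarray | None = None,
) -> tuple[PLSRModel, LVSelection]:
    """Fit PLS1 with the LV count minimizing leave-one-out RMSE.

    ``max_lv`` is clipped to min(n-1, p).  Ties in the LOO curve resolve to
    the smallest LV count.
    """
    x = train.absorbance
    y = train.label.astype(float)
    n, p = x.shape
    max_lv = min(max_lv, n - 1, p)
    if max_lv < 1:
        raise ValueError("not enough samples/variables for one latent variable")
    cand = np.arange(1, max_lv + 1) if candidates is None else np.asarray(candidates)

    # one LOO fit per sample, predictions recorded at every candidate A
    preds = np.full((n, cand.size), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            keep = np.arange(n) != i
            w, pl, q, _, xm, ym, got = nipals_pls1(x[keep], y[keep],
                                                   min(max_lv, n - 2))
            xc = x[i] - xm
            for j, a in enumerate(cand):
                a_eff = min(int(a), got)
                preds[i, j] = ym + xc @ _beta_from(w, pl, q, a_eff)
    rmse_loo = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(cand[int(np.argmin(rmse_loo))])

    w, pl, q, s_a, xm, ym, got = nipals_pls1(x, y, chosen)
    chosen = got
    beta = _beta_from(w, pl, q, chosen)
    model = PLSRModel(
        weights=w, x_loadings=pl, y_loadings=q, beta=beta,
        x_mean=xm, y_mean=ym, n_components=chosen,
        s_a=s_a, vip=np.empty(0), wavenumbers=train.wavenumbers.copy(),
    )
    model.vip = vip_scores(model)
    return model, LVSelection(candidates=cand, rmse_loo=rmse_loo, chosen=chosen)


def vip_scores(m: PLSRModel) -> np.ndarray:
    """Wold VIP per wavenumber; mean squared VIP is 1 by construction."""
    s_total = float(m.s_a.sum())
    if s_total <= 0:
        raise ValueError("no y-variance explained; VIP undefined")
    w_norm2 = (m.weights / np.linalg.norm(m.weights, axis=0, keepdims=True)) ** 2
    p = m.weights.shape[0]
    return np.sqrt(p * (w_norm2 @ m.s_a) / s_total)


def predict(m: PLSRModel, data: SpectraSet) -> np.ndarray:
    """Continuous prediction yhat = y_mean + (x - x_mean)' beta."""
    if data.p != m.x_mean.size or not np.allclose(data.wavenumbers, m.wavenumbers):
        raise ValueError("wavenumber axis differs from the training axis")
    return m.y_mean + (data.absorbance - m.x_mean) @ m.beta


def predict_and_classify(m: PLSRModel, data: SpectraSet) -> tuple[np.ndarray, np.ndarray]:
    """Continuous prediction plus the strict >0.5 class call (1 when above)."""
    yhat = predict(m, data)
    return yhat, (yhat > 0.5).astype(int)


def training_rmse(m: PLSRModel, train: SpectraSet) -> float:
    return rmse(train.label.astype(float), predict(m, train))
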