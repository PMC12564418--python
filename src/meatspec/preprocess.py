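"""The eleven spectral pre-processing operators, as composable transforms.

Stateless operators (SNV, detrend, Savitzky-Golay derivatives, deresolve,
median filter, ATR correction) act row-by-row.  Stateful operators (MSC,
quantile normalization, OSC) carry fit-time state and must be fit on
training rows only, then applied to both partitions — the
:class:`FittedTransform` / :func:`apply_pipeline` machinery enforces that,
so no information from held-out rows leaks into the transform.

Transform registry (the names used throughout the factorial experiment):

====================  =========================================================
``raw``               no treatment
``sg1``               Savitzky-Golay 1st derivative (window 11, polyorder 2)
``sg2``               Savitzky-Golay 2nd derivative (window 15, polyorder 3)
``deresolve``         SG smoothing followed by SG 1st derivative
``detrend``           least-squares polynomial baseline removal (degree 1)
``median5``           5-point sliding median, reflect padding
``msc``               multiplicative scatter correction against the train mean
``osc``               orthogonal signal correction (1 component)
``quantile``          quantile normalization to the train rank-mean reference
``snv``               standard normal variate (row mean 0, sd 1, n-1 denom.)
``snv_detrend``       SNV then degree-2 detrend
``atr_correct``       wavenumber-proportional penetration-depth rescaling
====================  =========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import median_filter as _nd_median
from scipy.signal import savgol_filter

from .io import SpectraSet

__all__ = [
    "PreprocessSpec",
    "FittedTransform",
    "PreprocessError",
    "sg_derivative",
    "snv",
    "msc_fit",
    "msc_fit_apply",
    "detrend",
    "median_filter5",
    "quantile_fit",
    "quantile_normalize",
    "osc_fit",
    "osc_fit_apply",
    "deresolve",
    "atr_correct",
    "snv_detrend",
    "apply_pipeline",
    "PAPER_PREPROCESSORS",
]

PAPER_PREPROCESSORS = (
    "raw", "sg1", "sg2", "deresolve", "detrend", "median5",
    "msc", "osc", "quantile", "snv", "snv_detrend",
)

STATEFUL = frozenset({"msc", "osc", "quantile"})


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessSpec:
    """A named transform plus its parameter map."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(PAPER_PREPROCESSORS) | {"atr_correct"}
        if self.name not in valid:
            raise PreprocessError(f"unknown preprocessing transform {self.name!r}")
        p = self.params
        if self.name in ("sg1", "sg2", "deresolve"):
            window = p.get("window")
            polyorder = p.get("polyorder")
            if window is not None and window % 2 == 0:
                raise PreprocessError("SG window must be odd")
            if window is not None and polyorder is not None and polyorder >= window:
                raise PreprocessError("SG polyorder must be < window")
        if self.name == "median5" and p.get("width", 5) % 2 == 0:
            raise PreprocessError("median filter width must be odd")
        if self.name == "osc" and p.get("n_components", 1) < 0:
            raise PreprocessError("osc n_components must be >= 0")


def _uniform_segments(w: np.ndarray, min_len: int) -> tuple[list[slice], float]:
    """Split an ascending axis into contiguous uniformly spaced segments.

    Region masking cuts bands (e.g. atmospheric CO2) out of an otherwise
    uniform instrument grid, leaving gaps; axis-dependent filters are applied
    per segment and never bridge a gap.  A segment whose internal spacing is
    non-uniform beyond 1e-9 relative, or shorter than ``min_len``, raises.
    """
    dw = np.diff(w)
    if dw.size == 0:
        raise PreprocessError("need at least two wavenumber points")
    base = float(np.min(dw))
    breaks = np.flatnonzero(dw > base * 1.5)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [w.size]))
    segments = [slice(int(a), int(b)) for a, b in zip(starts, ends)]
    for seg in segments:
        if seg.stop - seg.start < min_len:
            raise PreprocessError(
                "wavenumber grid is not uniform: a contiguous segment is "
                f"shorter than the filter window ({min_len} points)"
            )
        dseg = np.diff(w[seg])
        if np.max(np.abs(dseg - base)) > 1e-9 * base:
            raise PreprocessError("wavenumber grid is not uniform; filter undefined")
    return segments, base


def sg_derivative(s: SpectraSet, order: int, window: int | None = None,
                  polyorder: int | None = None) -> SpectraSet:
    """Savitzky-Golay derivative along the wavenumber axis (AU per cm^-1).

    On a gap-carrying axis (excluded bands) the filter runs independently on
    each contiguous uniformly spaced segment.
    """
    if order not in (0, 1, 2):
        raise PreprocessError("derivative order must be 0, 1 or 2")
    if window is None:
        window = {0: 11, 1: 11, 2: 15}[order]
    if polyorder is None:
        polyorder = {0: 2, 1: 2, 2: 3}[order]
    if window % 2 == 0:
        raise PreprocessError("SG window must be odd")
    if polyorder >= window:
        raise PreprocessError("SG polyorder must be < window")
    if polyorder < order:
        raise PreprocessError("SG polyorder must be >= derivative order")
    segments, delta = _uniform_segments(s.wavenumbers, window)
    out = np.empty_like(s.absorbance)
    for seg in segments:
        out[:, seg] = savgol_filter(
            s.absorbance[:, seg], window_length=window, polyorder=polyorder,
            deriv=order, delta=delta if order > 0 else 1.0, axis=1, mode="interp",
        )
    return s.with_absorbance(out)


def snv(s: SpectraSet) -> SpectraSet:
    """Row-wise standard normal variate: mean 0, sd 1 (n-1 denominator)."""
    x = s.absorbance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() < 1e-300)
    if degenerate.size:
        i = int(degenerate[0])
        raise PreprocessError(
            f"row {i} (sample_id={s.sample_id[i]!r}) is constant; SNV undefined"
        )
    return s.with_absorbance((x - mu) / sd)


def msc_fit(train: SpectraSet) -> np.ndarray:
    """MSC reference spectrum = column-wise mean of the training rows."""
    return train.absorbance.mean(axis=0)


def _msc_apply(s: SpectraSet, reference: np.ndarray) -> SpectraSet:
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 0:
        raise PreprocessError("MSC reference spectrum is constant")
    x = s.absorbance
    # per-row OLS of x on [1, ref]
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-10):
        i = int(np.flatnonzero(np.abs(b) < 1e-10)[0])
        raise PreprocessError(f"degenerate MSC fit for row {i}: slope ~ 0")
    a = x.mean(axis=1) - b * ref.mean()
    return s.with_absorbance((x - a[:, None]) / b[:, None])


def msc_fit_apply(train: SpectraSet, apply_to: SpectraSet) -> SpectraSet:
    return _msc_apply(apply_to, msc_fit(train))


def _poly_basis(w: np.ndarray, degree: int) -> np.ndarray:
    # scale axis to [-1, 1] for conditioning
    t = (w - w.mean()) / max(np.ptp(w) / 2, 1e-300)
    return np.vander(t, degree + 1, increasing=True)


def detrend(s: SpectraSet, degree: int = 1) -> SpectraSet:
    """Subtract each row's least-squares polynomial in wavenumber."""
    if degree < 0:
        raise PreprocessError("detrend degree must be >= 0")
    if degree >= s.p:
        raise PreprocessError(f"detrend degree {degree} >= number of columns {s.p}")
    basis = _poly_basis(s.wavenumbers, degree)
    q, _ = np.linalg.qr(basis)
    x = s.absorbance
    return s.with_absorbance(x - (x @ q) @ q.T)


def median_filter5(s: SpectraSet, width: int = 5) -> SpectraSet:
    """Sliding median per row with reflect padding."""
    if width % 2 == 0:
        raise PreprocessError("median filter width must be odd")
    if width > s.p:
        raise PreprocessError("median filter width exceeds spectrum length")
    segments, _ = _uniform_segments(s.wavenumbers, width)
    out = np.empty_like(s.absorbance)
    for seg in segments:
        out[:, seg] = _nd_median(s.absorbance[:, seg], size=(1, width), mode="reflect")
    return s.with_absorbance(out)


def quantile_fit(train: SpectraSet) -> np.ndarray:
    """Reference distribution: mean across training rows of per-rank sorted values."""
    if train.n < 2:
        raise PreprocessError("quantile normalization needs >= 2 training rows")
    return np.sort(train.absorbance, axis=1).mean(axis=0)


def _quantile_apply(s: SpectraSet, reference: np.ndarray) -> SpectraSet:
    ref = np.asarray(reference, dtype=float)
    if ref.size != s.p:
        raise PreprocessError("quantile reference length mismatch")
    x = s.absorbance
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        order = np.argsort(x[i], kind="stable")
        row = ref.copy()
        # average reference values over tied ranks
        vals = x[i][order]
        ties = np.flatnonzero(vals[1:] == vals[:-1])
        if ties.size:
            j = 0
            m = vals.size
            while j < m:
                k = j
                while k + 1 < m and vals[k + 1] == vals[j]:
                    k += 1
                if k > j:
                    row[j:k + 1] = row[j:k + 1].mean()
                j = k + 1
        out[i, order] = row
    return s.with_absorbance(out)


def quantile_normalize(train: SpectraSet, apply_to: SpectraSet) -> SpectraSet:
    return _quantile_apply(apply_to, quantile_fit(train))


def _first_pc_score(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    u, sv, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, 0] * sv[0]


def osc_fit(train: SpectraSet, y: np.ndarray, n_components: int = 1,
            max_iter: int = 500, tol: float = 1e-10):
    """Fit Wold-style orthogonal signal correction components.

    Iteratively finds score vectors of X orthogonalized against y, with
    weight/loading vectors fit by least squares, and deflates X by the outer
    products.  Returns ``(x_mean, weights, loadings, scores, n_removed)``
    where columns pair up per removed component; ``scores`` holds the exact
    training score vectors used for deflation (orthogonal to y).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != train.n:
        raise PreprocessError("y length does not match training rows")
    if n_components < 0:
        raise PreprocessError("n_components must be >= 0")
    x = train.absorbance.astype(float).copy()
    x_mean = x.mean(axis=0)
    x = x - x_mean
    yc = y - y.mean()
    yty = float(yc @ yc)
    ws, ps, ts = [], [], []
    for _ in range(n_components):
        if float(np.sum(x * x)) < 1e-12:
            warnings.warn(
                f"OSC stopped early: only {len(ws)} component(s) had variance",
                stacklevel=2,
            )
            break
        t = _first_pc_score(x)
        w = np.zeros(train.p)
        for _ in range(max_iter):
            # project out the part of t predictable from y
            t_orth = t - yc * (float(yc @ t) / yty) if yty > 0 else t
            w_new = x.T @ t_orth
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-300:
                break
            w_new /= nrm
            t_new = x @ w_new
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t), 1e-300):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        # final orthogonalization: the removed score is exactly y-orthogonal
        if yty > 0:
            t = t - yc * (float(yc @ t) / yty)
        tt = float(t @ t)
        if tt < 1e-12:
            warnings.warn(
                f"OSC stopped early: only {len(ws)} component(s) had variance",
                stacklevel=2,
            )
            break
        p_load = x.T @ t / tt
        x = x - np.outer(t, p_load)
        ws.append(w)
        ps.append(p_load)
        ts.append(t)
    weights = np.column_stack(ws) if ws else np.zeros((train.p, 0))
    loadings = np.column_stack(ps) if ps else np.zeros((train.p, 0))
    scores = np.column_stack(ts) if ts else np.zeros((train.n, 0))
    return x_mean, weights, loadings, scores, len(ws)


def _osc_apply(s: SpectraSet, x_mean: np.ndarray, weights: np.ndarray,
               loadings: np.ndarray) -> SpectraSet:
    x = s.absorbance - x_mean
    for a in range(weights.shape[1]):
        t = x @ weights[:, a]
        x = x - np.outer(t, loadings[:, a])
    return s.with_absorbance(x + x_mean)


def osc_fit_apply(train: SpectraSet, y: np.ndarray, n_components: int,
                  apply_to: SpectraSet) -> SpectraSet:
    if n_components == 0:
        return apply_to.with_absorbance(apply_to.absorbance.copy())
    x_mean, w, p, _, _ = osc_fit(train, y, n_components)
    return _osc_apply(apply_to, x_mean, w, p)


def deresolve(s: SpectraSet, window: int | None = None,
              polyorder: int | None = None) -> SpectraSet:
    """Derivative with smoothing: SG smoothing pass, then SG 1st derivative."""
    smoothed = sg_derivative(s, order=0, window=window, polyorder=polyorder)
    return sg_derivative(smoothed, order=1, window=window, polyorder=polyorder)


def atr_correct(s: SpectraSet, reference_wavenumber: float = 1000.0) -> SpectraSet:
    """Rescale columns by nu/nu_ref to even out ATR penetration depth.

    Effective penetration depth in ATR scales with wavelength, inflating
    low-wavenumber absorbance; multiplying by nu/nu_ref undoes a linear
    version of that bias.
    """
    w = s.wavenumbers
    if not (w[0] <= reference_wavenumber <= w[-1]):
        raise PreprocessError(
            f"reference wavenumber {reference_wavenumber} outside axis "
            f"[{w[0]}, {w[-1]}]"
        )
    return s.with_absorbance(s.absorbance * (w / reference_wavenumber))


def snv_detrend(s: SpectraSet, degree: int = 2) -> SpectraSet:
    """SNV scaling followed by polynomial detrend (Barnes formulation)."""
    return detrend(snv(s), degree=degree)


@dataclass
class FittedTransform:
    """A transform frozen with its fit-time state (if any)."""

    spec: PreprocessSpec
    state: dict = field(default_factory=dict)

    def apply(self, s: SpectraSet) -> SpectraSet:
        name, p = self.spec.name, self.spec.params
        if name == "raw":
            return s
        if name == "sg1":
            return sg_derivative(s, 1, p.get("window"), p.get("polyorder"))
        if name == "sg2":
            return sg_derivative(s, 2, p.get("window"), p.get("polyorder"))
        if name == "deresolve":
            return deresolve(s, p.get("window"), p.get("polyorder"))
        if name == "detrend":
            return detrend(s, p.get("degree", 1))
        if name == "median5":
            return median_filter5(s, p.get("width", 5))
        if name == "snv":
            return snv(s)
        if name == "snv_detrend":
            return snv_detrend(s, p.get("degree", 2))
        if name == "atr_correct":
            return atr_correct(s, p.get("reference_wavenumber", 1000.0))
        if name == "msc":
            return _msc_apply(s, self.state["reference"])
        if name == "quantile":
            return _quantile_apply(s, self.state["reference"])
        if name == "osc":
            return _osc_apply(
                s, self.state["x_mean"], self.state["weights"], self.state["loadings"]
            )
        raise PreprocessError(f"unknown transform {name!r}")


def _fit_one(spec: PreprocessSpec, train: SpectraSet,
             y: np.ndarray | None) -> FittedTransform:
    if spec.name == "msc":
        return FittedTransform(spec, {"reference": msc_fit(train)})
    if spec.name == "quantile":
        return FittedTransform(spec, {"reference": quantile_fit(train)})
    if spec.name == "osc":
        if y is None:
            raise PreprocessError("OSC requires labels (y) at fit time")
        n_comp = spec.params.get("n_components", 1)
        if n_comp == 0:
            return FittedTransform(spec, {
                "x_mean": np.zeros(train.p),
                "weights": np.zeros((train.p, 0)),
                "loadings": np.zeros((train.p, 0)),
            })
        x_mean, w, p_load, _, _ = osc_fit(train, y, n_comp)
        return FittedTransform(spec, {"x_mean": x_mean, "weights": w, "loadings": p_load})
    return FittedTransform(spec)


def apply_pipeline(
    specs: list[PreprocessSpec | str],
    train: SpectraSet,
    test: SpectraSet | None = None,
) -> tuple[SpectraSet, SpectraSet | None, list[FittedTransform]]:
    """Fit stateful transforms on ``train`` only, apply the chain to both sets."""
    fitted: list[FittedTransform] = []
    cur_train, cur_test = train, test
    for spec in specs:
        if isinstance(spec, str):
            spec = PreprocessSpec(spec)
        y = cur_train.label.astype(float) if spec.name == "osc" else None
        ft = _fit_one(spec, cur_train, y)
        cur_train = ft.apply(cur_train)
        if cur_test is not None:
            cur_test = ft.apply(cur_test)
        fitted.append(ft)
    return cur_train, cur_test, fitted
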