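"""The factorial authentication experiment.

Runs every combination of preprocessing method (the eleven-treatment suite)
and spectral region (whole mid-IR and fingerprint) through the full model
stack — PCA variance, SIMCA, PCA-LDA, PLS-LDA, PLSR, RBF-SVR and the MLP —
under the three validation schemes, and emits one tidy results table per
model family.

Leakage discipline: replicate averaging and region masking are row-local
and happen once.  Outlier screening (T²/Q on the preprocessed cell data)
happens once per cell, mirroring a screening step done before modelling.
Inside every validation fold, stateful preprocessing (MSC, OSC, quantile)
is refit on the fold's training rows only.

Per-cell seeds are derived from the global seed by a CRC32 hash of
``"{seed}:{region}:{preprocess}"`` (masked to 31 bits), so any single cell
can be reproduced in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ann import ANNConfig, ANNModel, evaluate_ann, fit_ann
from .discriminant import fit_pca_lda, fit_pls_lda, predict as disc_predict
from .io import NAMED_REGIONS, SpectraSet, apply_region, average_replicates
from .metrics import rmse
from .pca import fit_pca, flag_outliers
from .plsr import fit_plsr, predict as plsr_predict
from .preprocess import PAPER_PREPROCESSORS, apply_pipeline
from .simca import evaluate_simca, fit_simca
from .svr import SVRConfig, fit_svr_grid, loo_rmse
from .validation import (SplitScheme, excluded_accuracy, loo_accuracy,
                         training_accuracy, venetian_split)

__all__ = ["ExperimentConfig", "run_experiment", "report_summary", "cell_seed"]

DISPLAY_NAMES = {
    "sg1": "1st Derivative", "sg2": "2nd Derivative", "deresolve": "Deresolve",
    "detrend": "Detrend", "median5": "Median Filter", "msc": "MSC",
    "osc": "OSC", "quantile": "Quantile Norm.", "raw": "Raw", "snv": "SNV",
    "snv_detrend": "SNV + Detrend", "atr_correct": "ATR Correction",
}


@dataclass
class ExperimentConfig:
    preprocessors: tuple = PAPER_PREPROCESSORS
    regions: tuple = ("whole", "fingerprint")
    models: tuple = ("pca", "simca", "pca_lda", "pls_lda", "plsr", "svr", "ann")
    remove_outliers: bool = True
    max_lv: int = 15
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        if d.get("preset") == "paper":
            d = {k: v for k, v in d.items() if k != "preset"}
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})


def cell_seed(seed: int, region: str, prep: str) -> int:
    return zlib.crc32(f"{seed}:{region}:{prep}".encode()) & 0x7FFFFFFF


class _PrepWrapped:
    """A classifier with its fold-local preprocessing chain baked in."""

    def __init__(self, specs, fit_fn, predict_fn, train: SpectraSet):
        ptrain, _, self._fitted = apply_pipeline(list(specs), train)
        self._inner = fit_fn(ptrain)
        self._predict_fn = predict_fn

    def _prep(self, data: SpectraSet) -> SpectraSet:
        for ft in self._fitted:
            data = ft.apply(data)
        return data

    def predict(self, data: SpectraSet):
        return self._predict_fn(self._inner, self._prep(data))

    @property
    def inner(self):
        return self._inner


def _simca_factory(specs):
    return lambda tr: _PrepWrapped(
        specs, fit_simca, lambda m, d: m.distances(d.absorbance).argmin(axis=1), tr
    )


def _lda_factory(specs, kind):
    fit = fit_pca_lda if kind == "pca_lda" else fit_pls_lda
    return lambda tr: _PrepWrapped(specs, fit, lambda m, d: disc_predict(m, d)[0], tr)


def _prep_cell(data: SpectraSet, specs, remove_outliers: bool):
    """Preprocess the whole cell, screen outliers, return filtered raw rows."""
    pdata, _, _ = apply_pipeline(list(specs), data)
    if not remove_outliers:
        return data, pdata, 0
    report, _ = flag_outliers(pdata)
    keep = ~report.flagged
    return data.rows(keep), pdata.rows(keep), report.n_flagged


def _run_cell(raw: SpectraSet, pdata: SpectraSet, specs, models, n_outliers,
              prep: str, region: str, seed: int, max_lv: int, rows: dict):
    scheme = SplitScheme()
    n = raw.n
    tr_idx, ex_idx = venetian_split(n, scheme.stride, scheme.offset)
    base = {"preprocess": DISPLAY_NAMES.get(prep, prep), "region": region}

    if "pca" in models:
        m = fit_pca(pdata, min(2, pdata.n - 1))
        rows["pca_variance"].append({
            **base,
            "pc1_pct": 100 * m.all_explained[0],
            "pc2_pct": 100 * (m.all_explained[1] if m.all_explained.size > 1 else 0.0),
            "outliers_removed": n_outliers,
        })

    if "simca" in models:
        factory = _simca_factory(specs)
        full = factory(raw)
        train_report = evaluate_simca(full.inner, full._prep(raw))
        loo_acc, _ = loo_accuracy(factory, raw)
        ex_acc, _ = excluded_accuracy(factory, raw, scheme)
        rows["simca"].append({
            **base,
            "training_accuracy": train_report.accuracy,
            "specificity": train_report.specificity,
            "selectivity": train_report.selectivity,
            "loo_accuracy": loo_acc / 100.0,
            "excluded_accuracy": ex_acc / 100.0,
            "outliers_removed": n_outliers,
        })

    for kind in ("pca_lda", "pls_lda"):
        if kind not in models:
            continue
        factory = _lda_factory(specs, kind)
        full = factory(raw)
        rows["discriminant"].append({
            **base, "model": kind,
            "training_accuracy": training_accuracy(full, raw),
            "loo_accuracy": loo_accuracy(factory, raw)[0],
            "excluded_accuracy": excluded_accuracy(factory, raw, scheme)[0],
        })

    if "plsr" in models:
        model, sel = fit_plsr(pdata, max_lv=max_lv)
        yhat_train = plsr_predict(model, pdata)
        y = pdata.label.astype(float)
        # excluded-row RMSE: the whole procedure (LV selection included)
        # refit on the venetian training partition
        ptr, pex, _ = apply_pipeline(list(specs),
                                     raw.rows(tr_idx), raw.rows(ex_idx))
        ex_model, _ = fit_plsr(ptr, max_lv=max_lv)
        rows["plsr"].append({
            **base,
            "r2": 1 - np.sum((y - yhat_train) ** 2) / np.sum((y - y.mean()) ** 2),
            "lv": model.n_components,
            "rmse_train": rmse(y, yhat_train),
            "rmse_loo": float(sel.rmse_loo[np.flatnonzero(sel.candidates == sel.chosen)[0]]
                              if np.any(sel.candidates == sel.chosen)
                              else sel.rmse_loo.min()),
            "rmse_excluded": rmse(pex.label.astype(float), plsr_predict(ex_model, pex)),
        })

    if "svr" in models:
        res = fit_svr_grid(pdata, SVRConfig(), seed=seed)
        loo_rmse(res, pdata)
        ptr, pex, _ = apply_pipeline(list(specs),
                                     raw.rows(tr_idx), raw.rows(ex_idx))
        ex_res = fit_svr_grid(ptr, SVRConfig(), seed=seed)
        rows["svr"].append({
            **base,
            "r2": res.r2_train,
            "rmse_train": res.rmse_train,
            "rmse_loo": res.rmse_loo,
            "rmse_excluded": rmse(pex.label.astype(float),
                                  ex_res.estimator.predict(pex.absorbance)),
        })

    if "ann" in models:
        cfg = ANNConfig(seed=seed)
        model = fit_ann(pdata, cfg)
        train_rep = model.training_report
        # excluded scheme: refit the selected architecture on the training part
        ptr, pex, _ = apply_pipeline(list(specs),
                                     raw.rows(tr_idx), raw.rows(ex_idx))
        ex_cfg = ANNConfig(hidden_layouts=(model.layout,),
                           max_iters=(model.max_iter,), seed=seed)
        ex_model = fit_ann(ptr, ex_cfg)
        ex_rep = evaluate_ann(ex_model, pex, scheme="excluded")
        for rep, which in ((train_rep, "train"), (ex_rep, "excluded")):
            rows["ann"].append({
                **base, "set": which,
                "accuracy": rep.accuracy, "precision": rep.precision,
                "recall": rep.recall, "specificity": rep.specificity,
                "f1": rep.f1, "misclassification_pct": rep.misclassification_pct,
                "cross_entropy": rep.extras["cross_entropy"],
                "auc": rep.extras["auc"],
                "layout": "-".join(map(str, model.layout)),
                "max_iter": model.max_iter,
            })


def run_experiment(data: SpectraSet, config: ExperimentConfig | None = None):
    """Run the factorial grid; returns ``(tables, manifest)``.

    ``tables`` maps table name to a tidy DataFrame; ``manifest`` records the
    seed, cell statuses and software version.  Failing cells are recorded
    and skipped, never fatal here (the CLI turns failures into a nonzero
    exit).
    """
    config = config or ExperimentConfig()
    averaged = average_replicates(data)
    rows = {k: [] for k in ("pca_variance", "simca", "discriminant",
                            "plsr", "svr", "ann")}
    cells = []
    for region in config.regions:
        region_data = apply_region(averaged, NAMED_REGIONS[region])
        for prep in config.preprocessors:
            seed = cell_seed(config.seed, region, prep)
            status = "ok"
            specs = [prep]
            try:
                raw, pdata, n_out = _prep_cell(region_data, specs,
                                               config.remove_outliers)
                _run_cell(raw, pdata, specs, config.models, n_out,
                          prep, region, seed, config.max_lv, rows)
            except Exception as e:  # noqa: BLE001 -- cell isolation is the contract
                status = f"failed: {e}"
            cells.append({"region": region, "preprocess": prep,
                          "seed": seed, "status": status})

    tables = {name: pd.DataFrame(rs) for name, rs in rows.items() if rs}
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "n_rows_input": int(data.n),
        "n_samples": int(averaged.n),
        "regions": list(config.regions),
        "preprocessors": list(config.preprocessors),
        "models": list(config.models),
        "cells": cells,
        "n_failed": sum(c["status"] != "ok" for c in cells),
    }
    return tables, manifest


_BEST_KEYS = {
    "simca": ("excluded_accuracy", True),
    "discriminant": ("excluded_accuracy", True),
    "plsr": ("rmse_excluded", False),
    "svr": ("rmse_excluded", False),
    "pca_variance": ("pc1_pct", True),
}


def report_summary(tables: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best cell per model family plus a heatmap-style accuracy matrix.

    Ties resolve to fewer components/LVs where tabulated, then to the
    lexically first preprocessing name.
    """
    if not tables or all(df.empty for df in tables.values()):
        raise ValueError("no result tables to summarize")
    best_rows = []
    for name, df in tables.items():
        if df.empty:
            continue
        if name == "ann":
            sub = df[df["set"] == "excluded"]
            if sub.empty:
                continue
            key, desc = "accuracy", True
            df = sub
        elif name in _BEST_KEYS:
            key, desc = _BEST_KEYS[name]
        else:
            continue
        work = df.copy()
        tie_cols = [c for c in ("lv",) if c in work.columns]
        work = work.sort_values(
            by=[key] + tie_cols + ["preprocess"],
            ascending=[not desc] + [True] * len(tie_cols) + [True],
            kind="stable",
        )
        top = work.iloc[0]
        best_rows.append({"table": name, "metric": key,
                          "value": float(top[key]),
                          "preprocess": top["preprocess"],
                          "region": top["region"]})
    best = pd.DataFrame(best_rows)

    heat = pd.DataFrame()
    if "discriminant" in tables and not tables["discriminant"].empty:
        heat = tables["discriminant"].pivot_table(
            index="preprocess", columns=["model", "region"],
            values="excluded_accuracy",
        )
        heat.columns = ["_".join(c) for c in heat.columns]
        heat = heat.reset_index()
    return best, heat
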