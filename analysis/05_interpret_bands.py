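#!/usr/bin/env python
"""Which wavenumbers drive the discrimination?

Three independent attributions on the fingerprint region:
  * PLSR: VIP scores (bands with VIP > 1) and beta coefficients,
  * RBF-SVR: top-30 permutation-importance wavenumbers,
  * MLP: region-of-importance (ROI) curve from block permutation.
Each is written as a CSV against the wavenumber axis.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from meatspec.ann import ANNConfig, fit_ann, roi_mapping
from meatspec.io import (FINGERPRINT_REGION, apply_region, average_replicates,
                         read_spectra_csv)
from meatspec.plsr import fit_plsr
from meatspec.svr import fit_svr_grid, permutation_importance

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/synthetic_spectra.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

fp = apply_region(average_replicates(read_spectra_csv(args.data)),
                  FINGERPRINT_REGION)
args.out.mkdir(parents=True, exist_ok=True)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")

    plsr_model, _ = fit_plsr(fp, max_lv=10)
    pd.DataFrame({
        "wavenumber": fp.wavenumbers,
        "beta": plsr_model.beta,
        "vip": plsr_model.vip,
    }).to_csv(args.out / "plsr_vip.csv", index=False)
    important = fp.wavenumbers[plsr_model.vip > 1]
    print(f"PLSR ({plsr_model.n_components} LVs): {important.size} wavenumbers "
          f"with VIP > 1; strongest at "
          f"{fp.wavenumbers[int(np.argmax(plsr_model.vip))]:.0f} cm^-1")

    svr_res = fit_svr_grid(fp, seed=args.seed)
    permutation_importance(svr_res, fp, repeats=10, seed=args.seed)
    pd.DataFrame({
        "wavenumber": fp.wavenumbers,
        "importance_mean": svr_res.importance_mean,
        "importance_sd": svr_res.importance_sd,
    }).to_csv(args.out / "svr_importance.csv", index=False)
    print(f"SVR best {svr_res.best}: top wavenumbers "
          f"{np.round(svr_res.top30[:5]).astype(int).tolist()} cm^-1")

    ann_model = fit_ann(fp, ANNConfig(seed=args.seed))
    roi = roi_mapping(ann_model, fp, window=11, repeats=5, seed=args.seed)
    roi.to_frame().to_csv(args.out / "ann_roi.csv", index=False)
    peak = fp.wavenumbers[int(np.argmax(roi.normalized))]
    print(f"ANN {ann_model.layout}: ROI peak at {peak:.0f} cm^-1")
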