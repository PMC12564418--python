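#!/usr/bin/env python
"""Summarize the factorial results: best cell per model family and the
discriminant-accuracy heatmap matrix."""

import argparse
from pathlib import Path

import pandas as pd

from meatspec.pipeline import report_summary

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

tables = {
    p.stem: pd.read_csv(p)
    for p in sorted(args.results.glob("*.csv"))
    if p.stem in ("pca_variance", "simca", "discriminant", "plsr", "svr", "ann")
}
best, heat = report_summary(tables)
best.to_csv(args.results / "summary_best.csv", index=False)
print("best cell per model family:")
print(best.to_string(index=False))
if not heat.empty:
    heat.to_csv(args.results / "summary_heatmap.csv", index=False)
    print(f"\nwrote heatmap matrix ({heat.shape[0]} preprocessing rows)")
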