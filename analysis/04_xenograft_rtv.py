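#!/usr/bin/env python
"""Relative-tumor-volume analysis of the synthetic xenograft study:
per-mouse RTV, responder fractions per arm, and pairwise two-sided
Mann-Whitney comparisons with significance tiers.

Writes results/rtv_per_group.csv and results/rtv_comparisons.csv."""

from pathlib import Path

import pandas as pd

import blisscreen as bs

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "scratch" / "inputs"
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

df = bs.read_tumor_table(INPUTS / "tumors.csv")
table = bs.rtv_table(df, treatment_start_day=0.0)
summary = (
    table.groupby("group")
    .agg(n=("rtv", "size"), median_rtv=("rtv", "median"),
         responders=("response", "sum"))
    .reset_index()
)
summary["responder_pct"] = 100.0 * summary["responders"] / summary["n"]
summary.to_csv(RESULTS / "rtv_per_group.csv", index=False, float_format="%.4f")

comps = bs.compare_all_groups(table)
comps.to_csv(RESULTS / "rtv_comparisons.csv", index=False, float_format="%.6g")
bs.growth_curve_summary(df).to_csv(ROOT / "scratch" / "growth_curves.csv", index=False)

for row in summary.itertuples():
    print(f"{row.group:<12} median RTV {row.median_rtv:6.2f}   "
          f"responders {row.responders}/{row.n} ({row.responder_pct:.1f}%)")
for row in comps.itertuples():
    print(f"{row.label_a} vs {row.label_b}: p={row.p_value:.4g} "
          f"[{row.method}] {row.stars}")
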