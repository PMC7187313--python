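#!/usr/bin/env python
"""Evaluate the quota-setting strategy behind the simulated decisions.

Aggregates (previous census, set quota) pairs per country grouping from
the step-01 dataset and fits both decision regressions: strict
proportional (no intercept) and threshold-with-increasing-proportion.
Reports the coefficient posteriors, the implied no-harvest threshold
-b0/b1 with P(threshold <= 0), and the probability that the threshold
model's slope is steeper. Writes summaries under results/quota/.

Usage: python analysis/04_quota_strategy.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

import lynxcast as lx
from lynxcast import io as lio
from lynxcast.quota import compare_slopes

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/monitoring.csv"))
parser.add_argument("--out", type=Path, default=Path("results/quota"))
args = parser.parse_args()

data = lio.read_monitoring_csv(args.data)
args.out.mkdir(parents=True, exist_ok=True)
settings = lx.FitSettings(n_chains=3, n_iter=12000, n_burnin=4000, thin=4,
                          seed=args.seed)

rows = []
for label, areas in (("sweden", [1]), ("norway", [2, 3])):
    series = lio.quota_series_from_dataset(data, areas=areas)
    prop = lx.fit_quota_model(series, "proportional", settings=settings)
    thr = lx.fit_quota_model(series, "threshold", settings=settings)
    summary = lx.threshold_summary(thr)
    p_steeper = compare_slopes(thr, prop, seed=args.seed)
    prop.summary().to_csv(args.out / f"{label}_proportional.csv")
    thr.summary().to_csv(args.out / f"{label}_threshold.csv")
    rows.append(
        {
            "group": label,
            "pairs": len(series),
            "prop_slope": float(prop.b1.mean()),
            "thr_slope": float(thr.b1.mean()),
            "threshold_mean": summary["mean"],
            "threshold_sd": summary["sd"],
            "P_threshold_leq_0": summary["p_leq_0"],
            "P_slope2_gt_slope1": p_steeper,
        }
    )

overview = pd.DataFrame(rows)
overview.to_csv(args.out / "strategy_overview.csv", index=False)
print(overview.round(3).to_string(index=False))
print("\nA clearly positive threshold with steep post-threshold slope "
      "identifies a de facto threshold strategy; P(threshold <= 0) near "
      "zero says the no-harvest zone is real, not noise.")
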