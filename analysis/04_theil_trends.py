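#!/usr/bin/env python
"""Theil decomposition trends on the synthetic panel.

For each resource and year, decomposes the population-weighted Theil index
into within- and between-region parts with contribution rates.  Writes tidy
series under results/ and figures under results/figures/.  Requires
03_simulate_panel.py to have run (regenerates the panel if absent).
"""

from pathlib import Path

import pandas as pd

from healtheil import theil as th
from healtheil.data_model import RESOURCES, RegionPartition, read_panel
from healtheil.synthetic_data import SimulationConfig, simulate_panel

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel_csv = OUT / "synthetic_panel.csv"
    if panel_csv.exists():
        panel = read_panel(panel_csv)
    else:
        panel = simulate_panel(SimulationConfig(seed=20130))

    trend_parts, region_parts, rate_parts = [], [], []
    for resource in RESOURCES:
        series = th.theil_trend(panel, resource)
        trend_parts.append(th.trend_frame(series))
        region_parts.append(th.region_within_frame(series))
        rate_parts.append(th.contribution_frame(series))
    trend = pd.concat(trend_parts, ignore_index=True)
    region = pd.concat(region_parts, ignore_index=True)
    rates = pd.concat(rate_parts, ignore_index=True)
    trend.to_csv(OUT / "theil_trend.csv", index=False)
    region.to_csv(OUT / "theil_by_region.csv", index=False)
    rates.to_csv(OUT / "contribution_rates.csv", index=False)

    totals = trend[trend.component == "total"].pivot(
        index="year", columns="resource", values="value"
    )
    print("Total Theil index by year:")
    print(totals.round(4))
    final = rates[rates.year == rates.year.max()].pivot(
        index="component", columns="resource", values="contribution_rate"
    )
    print("\nContribution rates in the final year:")
    print(final.round(3))
    dominant = final.drop(index="between").mean(axis=1).idxmax()
    print(
        f"\nOn this panel the {dominant} region carries the largest average"
        " within-group contribution. A group's rate is its internal Theil"
        " weighted by its population share, so both dispersion (highest in"
        " the west by default) and population weight (largest in the east)"
        " matter; drift leaves relative shares, and hence the Theil level,"
        " nearly constant across years."
    )


if __name__ == "__main__":
    main()
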