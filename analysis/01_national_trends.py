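#!/usr/bin/env python
"""National totals 2013-2018: per-10,000 densities and growth rates.

Computes the per-capita density of each public-health resource from the
packaged national-total counts, and the 2013→2018 percent change in both
the table-rounded convention (matching printed yearbook tables) and on
unrounded densities.  Writes results/national_densities.csv and
results/national_percent_changes.csv.
"""

from pathlib import Path

import pandas as pd

from healtheil import indicators as ind
from healtheil.data_model import RESOURCES, paper_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel = paper_fixture("totals_2013_2018")
    table = ind.density_table(panel)

    rows = []
    for year in panel.years:
        for resource in RESOURCES:
            value = table.value(year, "TOTAL", resource)
            rows.append(
                {"year": year, "resource": resource,
                 "per_10k": value, "per_10k_2dp": ind.round_half_away(value, 2)}
            )
    dens = pd.DataFrame(rows)
    dens.to_csv(OUT / "national_densities.csv", index=False)

    changes = []
    for resource in RESOURCES:
        start = table.value(2013, "TOTAL", resource)
        end = table.value(2018, "TOTAL", resource)
        changes.append(
            {"resource": resource,
             "pct_change_table_rounded": round(ind.percent_change(start, end), 2),
             "pct_change_raw": round(ind.percent_change(start, end, mode="raw"), 2)}
        )
    pct = pd.DataFrame(changes)
    pct.to_csv(OUT / "national_percent_changes.csv", index=False)

    print("Per-10,000 densities (2-dp display convention):")
    print(dens.pivot(index="year", columns="resource", values="per_10k_2dp"))
    print("\n2013→2018 percent changes:")
    print(pct.to_string(index=False))
    print(
        "\nEvery resource grew per capita except institutions, which fell by"
        f" {abs(pct.loc[pct.resource == 'institutions', 'pct_change_table_rounded'].iloc[0]):.2f}%"
        " (an institutional-merger period); equipment grew fastest."
    )


if __name__ == "__main__":
    main()
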