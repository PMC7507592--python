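#!/usr/bin/env python
"""Provincial 2018 snapshot: extremes and max/min ratios per perspective.

Summarizes the packaged 31-province density table from both the population
(per 10,000 capita) and geographic (per km²) perspectives.  Writes
results/extremes_2018.csv.
"""

from pathlib import Path

import pandas as pd

from healtheil import indicators as ind
from healtheil.data_model import paper_fixture

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = ind.DensityTable.from_density_panel(paper_fixture("provinces_2018"))

    rows = []
    for resource in ("institutions", "technical_personnel", "beds"):
        for perspective in ("per_10k", "per_km2"):
            s = ind.extremes(table, resource, perspective, 2018)
            rows.append(
                {"resource": s.resource, "perspective": s.perspective,
                 "min_province": s.min_province, "min_value": s.min_value,
                 "max_province": s.max_province, "max_value": s.max_value,
                 "max_min_ratio": s.max_min_ratio}
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "extremes_2018.csv", index=False)
    print(frame.to_string(index=False))
    print(
        "\nPer-capita spreads are modest (institutions span"
        " 0.045 Shanghai – 0.529 Gansu, ~12x), while geographic spreads are"
        " extreme: technical personnel per km² differ ~1403x between Shanghai"
        " and Tibet on printed 3-dp values."
    )


if __name__ == "__main__":
    main()
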