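"""Per-capita and per-area density indicators and trend/extremes summaries.

Densities are resource counts divided by population (per 10,000 persons) or
by land area (per km²).  Published tables print per-10,000 values at 2
decimals for national totals and 3 decimals for provinces; rounding is
half-away-from-zero throughout to match that convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .data_model import RESOURCES, ResourcePanel

TOTAL_LABEL = "TOTAL"


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (the convention of printed yearbook tables).

    Python's built-in ``round`` is banker's rounding, which disagrees with
    printed tables on exact-half digits.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def density_per_capita(count: float, population: float) -> float:
    """Resource units per 10,000 persons: ``count / population`` with the
    population already in 10,000-person units.  Unrounded."""
    if not population > 0:
        raise ValueError(f"population must be > 0, got {population}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / population


def density_display(value: float, convention: str = "totals") -> float:
    """Round a density for display: 2 dp ("totals") or 3 dp ("provinces")."""
    decimals = {"totals": 2, "provinces": 3}[convention]
    return round_half_away(value, decimals)


def percent_change(start: float, end: float, mode: str = "table_rounded") -> float:
    """Percent change 100*(end-start)/start between two densities.

    ``table_rounded`` first rounds both densities to 2 decimals; this is the
    convention under which the published growth percentages (e.g. +8.72% for
    technical personnel, −43.48% for institutions over 2013–2018) are exactly
    reproducible.  ``raw`` uses the unrounded densities.
    """
    if mode not in ("table_rounded", "raw"):
        raise ValueError(f"mode must be 'table_rounded' or 'raw', got {mode!r}")
    if mode == "table_rounded":
        start, end = round_half_away(start, 2), round_half_away(end, 2)
        if start == 0:
            raise ValueError(
                "start density rounds to 0 at 2 decimals; use mode='raw'"
            )
    if not start > 0:
        raise ValueError(f"start density must be > 0, got {start}")
    return 100.0 * (end - start) / start


@dataclass(frozen=True)
class ExtremesSummary:
    resource: str
    perspective: str  # "per_10k" | "per_km2"
    year: int
    min_province: str
    min_value: float
    max_province: str
    max_value: float
    max_min_ratio: float | None  # None when min_value == 0 (undefined)


class DensityTable:
    """Tidy table of densities keyed by (year, province-or-TOTAL, resource).

    Backed by a DataFrame with columns ``year, province, resource, per_10k,
    per_km2`` (``per_km2`` may be NaN when areas are unknown).
    """

    COLUMNS = ("year", "province", "resource", "per_10k", "per_km2")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS[:4]) - set(frame.columns)
        if missing:
            raise ValueError(f"density table missing column(s): {sorted(missing)}")
        frame = frame.copy()
        if "per_km2" not in frame.columns:
            frame["per_km2"] = float("nan")
        self.frame = frame[list(self.COLUMNS)].sort_values(
            ["year", "resource", "province"], kind="stable"
        ).reset_index(drop=True)

    def value(self, year: int, province: str, resource: str, perspective: str = "per_10k") -> float:
        if perspective not in ("per_10k", "per_km2"):
            raise ValueError(f"perspective must be per_10k or per_km2, got {perspective!r}")
        sel = self.frame[
            (self.frame["year"] == year)
            & (self.frame["province"] == province)
            & (self.frame["resource"] == resource)
        ]
        if sel.empty:
            raise KeyError(f"no density for ({year}, {province!r}, {resource!r})")
        return float(sel.iloc[0][perspective])

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.frame["year"].unique()))

    @classmethod
    def from_density_panel(cls, panel: ResourcePanel) -> "DensityTable":
        """Wrap a density-flagged panel's stored printed densities."""
        if not panel.values_are_densities or panel.density_data is None:
            raise ValueError("panel does not carry pre-computed densities")
        return cls(panel.density_data)


def density_table(panel: ResourcePanel) -> DensityTable:
    """Compute the full density table from a counts panel.

    One row per (year, province, resource) with data, plus a national TOTAL
    row per (year, resource) aggregated by summing counts and populations
    before dividing (so the TOTAL equals the population-weighted mean of
    province densities).
    """
    if panel.values_are_densities:
        raise ValueError(
            "panel stores printed densities, not counts; use "
            "DensityTable.from_density_panel to read them directly"
        )
    rows = []
    for year in panel.years:
        subset = panel.subset(year)
        for resource in RESOURCES:
            seen = [(r, r.resource(resource)) for r in subset if r.resource(resource) is not None]
            if not seen:
                continue
            for rec, count in seen:
                rows.append(
                    {
                        "year": year,
                        "province": rec.province,
                        "resource": resource,
                        "per_10k": density_per_capita(count, rec.population),
                        "per_km2": (count / rec.area) if rec.area else float("nan"),
                    }
                )
            total_count = sum(c for _, c in seen)
            total_pop = sum(r.population for r, _ in seen)
            areas = [r.area for r, _ in seen]
            total_area = sum(areas) if all(a is not None for a in areas) else None
            rows.append(
                {
                    "year": year,
                    "province": TOTAL_LABEL,
                    "resource": resource,
                    "per_10k": density_per_capita(total_count, total_pop),
                    "per_km2": (total_count / total_area) if total_area else float("nan"),
                }
            )
    return DensityTable(pd.DataFrame(rows, columns=list(DensityTable.COLUMNS)))


def extremes(
    table: DensityTable,
    resource: str,
    perspective: str = "per_10k",
    year: int | None = None,
    provinces: tuple[str, ...] | None = None,
) -> ExtremesSummary:
    """Min/max provinces and their ratio for one (year, resource, perspective).

    Ratios are taken on the stored (printed-precision) values.  Ties break
    alphabetically by province name; a zero minimum yields an undefined
    (``None``) ratio rather than infinity.  ``provinces`` optionally
    restricts the comparison (e.g. to one region's members).
    """
    frame = table.frame
    if year is None:
        years = table.years()
        if len(years) != 1:
            raise ValueError("year must be given for a multi-year table")
        year = years[0]
    sel = frame[
        (frame["year"] == year)
        & (frame["resource"] == resource)
        & (frame["province"] != TOTAL_LABEL)
    ]
    if provinces is not None:
        sel = sel[sel["province"].isin(provinces)]
    sel = sel.dropna(subset=[perspective])
    if len(sel) < 2:
        raise ValueError(
            f"need >= 2 provinces with finite {perspective} values for "
            f"({year}, {resource}); got {len(sel)}"
        )
    sel = sel.sort_values("province", kind="stable")  # alphabetical tie-break
    values = sel[perspective].to_numpy()
    i_min = int(values.argmin())
    i_max = int(values.argmax())
    min_value = float(values[i_min])
    max_value = float(values[i_max])
    ratio = (max_value / min_value) if min_value > 0 else None
    return ExtremesSummary(
        resource=resource,
        perspective=perspective,
        year=int(year),
        min_province=str(sel.iloc[i_min]["province"]),
        min_value=min_value,
        max_province=str(sel.iloc[i_max]["province"]),
        max_value=max_value,
        max_min_ratio=ratio,
    )


def percent_change_table(
    table: DensityTable,
    start_year: int,
    end_year: int,
    mode: str = "table_rounded",
    province: str = TOTAL_LABEL,
) -> pd.DataFrame:
    """Percent change of each resource's per-10,000 density between two years."""
    rows = []
    for resource in RESOURCES:
        try:
            start = table.value(start_year, province, resource)
            end = table.value(end_year, province, resource)
        except KeyError:
            continue
        rows.append(
            {
                "resource": resource,
                "start_year": start_year,
                "end_year": end_year,
                "mode": mode,
                "percent_change": percent_change(start, end, mode=mode),
            }
        )
    return pd.DataFrame(rows)
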