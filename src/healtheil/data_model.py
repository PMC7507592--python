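"""Domain types, region partition, and CSV ingestion for provincial panels.

The unit of observation is one province in one calendar year, carrying its
resident population (in units of 10,000 persons, the yearbook convention),
land area in km², and counts of four public-health resources: institutions,
technical personnel, beds, and large equipment.  Provinces belong to one of
three macro-regions (western / middle / eastern), the grouping used for the
within/between inequality decomposition.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

RESOURCES: tuple[str, ...] = (
    "institutions",
    "technical_personnel",
    "beds",
    "equipment",
)

REGIONS: tuple[str, ...] = ("western", "middle", "eastern")

#: Canonical CSV column order used by every writer.
PANEL_COLUMNS: tuple[str, ...] = (
    "year",
    "province",
    "region",
    "population_10k",
    "area_km2",
) + RESOURCES

# The three-region grouping of the 31 mainland provinces, by geography and
# GDP per capita.  The westward romanization collision is resolved by using
# the distinct pinyin spellings: "Shaanxi" (western, capital Xi'an) versus
# "Shanxi" (middle, capital Taiyuan); see aliases below.
_WESTERN = (
    "Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Yunnan", "Tibet",
    "Gansu", "Shaanxi", "Guizhou", "Ningxia", "Qinghai", "Xinjiang",
)
_MIDDLE = (
    "Jilin", "Anhui", "Heilongjiang", "Henan", "Hubei", "Hunan", "Jiangxi",
    "Shanxi",
)
_EASTERN = (
    "Tianjin", "Beijing", "Guangdong", "Liaoning", "Hebei", "Shanghai",
    "Jiangsu", "Zhejiang", "Shandong", "Hainan", "Fujian",
)

#: Alternative spellings accepted on input, mapped to canonical names.
#: The bare spelling "Shanxi" is ambiguous in some sources (it is printed for
#: both the western and the middle province); it resolves to the canonical
#: middle-region Shanxi.  The western province must be spelled "Shaanxi".
PROVINCE_ALIASES: dict[str, str] = {
    "nei mongol": "Inner Mongolia",
    "neimenggu": "Inner Mongolia",
    "xizang": "Tibet",
    "xinjiang uyghur autonomous region": "Xinjiang",
    "xinjiang uygur autonomous region": "Xinjiang",
    "guangxi zhuang autonomous region": "Guangxi",
    "ningxia hui autonomous region": "Ningxia",
    "shaanxi (western)": "Shaanxi",
    "shanxi (middle)": "Shanxi",
}


class PanelError(ValueError):
    """Hard error raised for unusable inputs (missing columns, unknown names)."""


def _canon_key(name: str) -> str:
    return " ".join(str(name).split()).lower()


@dataclass(frozen=True)
class RegionPartition:
    """Mapping from canonical province name to one of three region labels."""

    mapping: Mapping[str, str]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.mapping.values())
        if len(labels) != 3:
            raise PanelError(
                f"a region partition needs exactly 3 labels, got {sorted(labels)}"
            )

    @classmethod
    def paper(cls) -> "RegionPartition":
        """The packaged 31-province partition: 12 western, 8 middle, 11 eastern."""
        mapping = {p: "western" for p in _WESTERN}
        mapping.update({p: "middle" for p in _MIDDLE})
        mapping.update({p: "eastern" for p in _EASTERN})
        return cls(mapping=mapping, aliases=dict(PROVINCE_ALIASES))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionPartition":
        frame = pd.read_csv(path)
        missing = {"province", "region"} - set(frame.columns)
        if missing:
            raise PanelError(f"partition file missing column(s): {sorted(missing)}")
        return cls(
            mapping=dict(zip(frame["province"].str.strip(), frame["region"].str.strip()))
        )

    def canonical_name(self, name: str) -> str:
        """Resolve a province name case-insensitively, via aliases if needed."""
        key = _canon_key(name)
        for canonical in self.mapping:
            if _canon_key(canonical) == key:
                return canonical
        if key in {_canon_key(a): a for a in self.aliases}:
            return self.aliases[{_canon_key(a): a for a in self.aliases}[key]]
        raise PanelError(f"unknown province name: {name!r}")

    def region_of(self, name: str) -> str:
        return self.mapping[self.canonical_name(name)]

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def region_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for region in self.mapping.values():
            sizes[region] = sizes.get(region, 0) + 1
        return sizes

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["province", "region"])
            for province, region in self.mapping.items():
                writer.writerow([province, region])


@dataclass
class ProvinceRecord:
    """One province-year observation.

    ``population`` is in units of 10,000 persons; ``area`` in km².  Resource
    fields are raw counts unless the containing panel is density-flagged.
    A ``region`` of ``None`` marks national-total rows that do not belong to
    any group.
    """

    province: str
    year: int
    population: float
    region: str | None = None
    area: float | None = None
    institutions: float | None = None
    technical_personnel: float | None = None
    beds: float | None = None
    equipment: float | None = None

    def resource(self, name: str) -> float | None:
        if name not in RESOURCES:
            raise KeyError(f"unknown resource {name!r}; valid: {RESOURCES}")
        return getattr(self, name)

    def problems(self) -> list[str]:
        out = []
        if not self.population > 0:
            out.append(f"population must be > 0, got {self.population}")
        if self.area is not None and not self.area > 0:
            out.append(f"area must be > 0 when present, got {self.area}")
        for name in RESOURCES:
            value = getattr(self, name)
            if value is not None and value < 0:
                out.append(f"{name} must be >= 0, got {value}")
        if self.region is not None and self.region not in REGIONS:
            out.append(f"region must be one of {REGIONS}, got {self.region!r}")
        return out


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors


@dataclass
class ResourcePanel:
    """A validated collection of province-year records plus a region partition.

    ``values_are_densities`` marks panels (such as the packaged 2018
    provincial table) whose resource fields hold printed per-10,000 densities
    rather than raw counts; count-consuming operations must reject them.
    ``density_data``, when present, is the tidy printed-density table with
    both per-10,000 and per-km² perspectives.
    """

    records: list[ProvinceRecord]
    partition: RegionPartition | None = None
    provenance: str = ""
    values_are_densities: bool = False
    validation: ValidationReport = field(default_factory=ValidationReport)
    density_data: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            locator = f"{rec.province}/{rec.year}"
            for msg in rec.problems():
                self.validation.errors.append((locator, msg))
            key = (rec.province, rec.year)
            if key in seen:
                self.validation.errors.append((locator, "duplicate (province, year)"))
            seen.add(key)
            if self.partition is not None and rec.region is not None:
                try:
                    expected = self.partition.region_of(rec.province)
                except PanelError:
                    expected = None
                if expected is not None and expected != rec.region:
                    self.validation.errors.append(
                        (locator, f"region {rec.region!r} disagrees with partition {expected!r}")
                    )
        by_year: dict[int, set[str]] = {}
        for rec in self.records:
            by_year.setdefault(rec.year, set()).add(rec.province)
        if len({frozenset(v) for v in by_year.values()}) > 1:
            self.validation.warnings.append(
                ("panel", "province sets differ across years (non-rectangular panel)")
            )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({rec.year for rec in self.records}))

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(sorted({rec.province for rec in self.records}))

    def subset(self, year: int) -> list[ProvinceRecord]:
        return [rec for rec in self.records if rec.year == year]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "year": rec.year,
                "province": rec.province,
                "region": rec.region,
                "population_10k": rec.population,
                "area_km2": rec.area,
                **{name: getattr(rec, name) for name in RESOURCES},
            }
            for rec in self.records
        ]
        frame = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
        return frame.sort_values(["year", "province"], kind="stable").reset_index(drop=True)


def _parse_number(raw: str) -> float | None:
    text = str(raw).strip().replace(",", "")
    if text == "" or text.lower() in {"nan", "na"}:
        return None
    return float(text)


def read_panel(
    path: str | Path,
    partition: RegionPartition | str | None = None,
    population_unit: str = "10k",
) -> ResourcePanel:
    """Read a long-format province-year CSV into a :class:`ResourcePanel`.

    ``partition`` may be a :class:`RegionPartition` (province names are then
    resolved and labelled through it), the literal string ``"from-file"`` (or
    ``None``) to take region labels from the CSV's ``region`` column, or a
    path to a two-column partition CSV.  ``population_unit`` is ``"10k"``
    (default) or ``"persons"`` (divided by 10,000 on ingest).  Numbers with
    thousands separators are tolerated.  Rows that fail to parse are dropped
    and reported in the attached :class:`ValidationReport`.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    if isinstance(partition, (str, Path)) and str(partition) != "from-file":
        partition = RegionPartition.from_csv(partition)
    use_file_regions = partition is None or partition == "from-file"

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip() for c in frame.columns]
    required = {"province", "year", "population_10k"}
    missing = required - set(frame.columns)
    if missing:
        raise PanelError(f"missing mandatory column(s): {sorted(missing)}")

    report = ValidationReport()
    records: list[ProvinceRecord] = []
    unknown: list[str] = []
    for idx, row in frame.iterrows():
        locator = f"row {idx + 2}"  # 1-based, counting the header
        province = str(row["province"]).strip()
        if not use_file_regions:
            try:
                province = partition.canonical_name(province)  # type: ignore[union-attr]
                region = partition.region_of(province)  # type: ignore[union-attr]
            except PanelError:
                unknown.append(province)
                continue
        else:
            region = str(row.get("region", "")).strip() or None
        try:
            year = int(_parse_number(row["year"]))  # type: ignore[arg-type]
            population = _parse_number(row["population_10k"])
            if population is None:
                raise ValueError("population is empty")
            if population_unit == "persons":
                population /= 10_000.0
            area = _parse_number(row.get("area_km2", ""))
            counts = {name: _parse_number(row.get(name, "")) for name in RESOURCES}
        except (TypeError, ValueError) as exc:
            report.errors.append((locator, f"non-numeric cell: {exc}"))
            continue
        records.append(
            ProvinceRecord(
                province=province, year=year, population=population,
                region=region, area=area, **counts,
            )
        )
    if unknown:
        raise PanelError(
            "province name(s) not in the supplied partition: " + ", ".join(sorted(set(unknown)))
        )
    resolved = partition if not use_file_regions else None
    return ResourcePanel(
        records=records,
        partition=resolved,  # type: ignore[arg-type]
        provenance=str(path),
        validation=report,
    )


def write_panel(panel: ResourcePanel, path: str | Path) -> None:
    """Write a panel back to CSV in the canonical column order."""
    frame = panel.to_frame()
    # Integer-valued floats print without a trailing .0 so fixtures round-trip.
    out = frame.copy()
    for col in ("population_10k", "area_km2", *RESOURCES):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else (f"{int(v)}" if float(v).is_integer() else repr(float(v)))
        )
    out.to_csv(path, index=False)


def _fixture_text(filename: str) -> io.StringIO:
    text = resources.files("healtheil.fixtures").joinpath(filename).read_text("utf-8")
    return io.StringIO(text)


FIXTURE_NAMES = ("totals_2013_2018", "provinces_2018")


def paper_fixture(name: str) -> ResourcePanel:
    """Load one of the packaged reference tables.

    ``"totals_2013_2018"`` — six national-total rows (2013–2018) with the
    yearbook population and raw resource counts.  ``"provinces_2018"`` — the
    31 provinces' printed per-10,000 densities for institutions, technical
    personnel and beds (no raw counts were published), returned as a
    density-flagged panel whose ``density_data`` also carries the per-km²
    perspective.
    """
    if name == "totals_2013_2018":
        frame = pd.read_csv(_fixture_text("totals_2013_2018.csv"))
        records = [
            ProvinceRecord(
                province=row["province"], year=int(row["year"]),
                population=float(row["population_10k"]),
                **{res: float(row[res]) for res in RESOURCES},
            )
            for _, row in frame.iterrows()
        ]
        return ResourcePanel(records=records, provenance="packaged: national totals 2013-2018")
    if name == "provinces_2018":
        frame = pd.read_csv(_fixture_text("provinces_2018_densities.csv"))
        partition = RegionPartition.paper()
        records = [
            ProvinceRecord(
                province=row["province"], year=int(row["year"]),
                region=row["region"],
                population=1.0,  # placeholder: the table prints densities, not counts
                institutions=float(row["institutions_per_10k"]),
                technical_personnel=float(row["technical_personnel_per_10k"]),
                beds=float(row["beds_per_10k"]),
            )
            for _, row in frame.iterrows()
        ]
        tidy_rows = []
        for _, row in frame.iterrows():
            for res in ("institutions", "technical_personnel", "beds"):
                tidy_rows.append(
                    {
                        "year": int(row["year"]),
                        "province": row["province"],
                        "resource": res,
                        "per_10k": float(row[f"{res}_per_10k"]),
                        "per_km2": float(row[f"{res}_per_km2"]),
                    }
                )
        return ResourcePanel(
            records=records,
            partition=partition,
            provenance="packaged: provincial densities 2018",
            values_are_densities=True,
            density_data=pd.DataFrame(tidy_rows),
        )
    raise PanelError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
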