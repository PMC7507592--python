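"""One-shot analysis report: densities → changes → extremes → Theil trends.

The JSON report is the canonical artifact; CSV tables and figures are
projections of it.  Every number in the report is produced by exactly one
call into :mod:`indicators` or :mod:`theil`, so report contents match direct
module calls bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import indicators, theil
from .data_model import RESOURCES, ResourcePanel

log = logging.getLogger("healtheil")


@dataclass
class ReportSettings:
    resources: tuple[str, ...] = RESOURCES
    zero_policy: str = "error"
    percent_mode: str = "table_rounded"
    extremes_perspectives: tuple[str, ...] = ("per_10k", "per_km2")


@dataclass
class AnalysisReport:
    metadata: dict[str, Any]
    densities: list[dict[str, Any]]
    percent_changes: list[dict[str, Any]]
    extremes: list[dict[str, Any]]
    theil_trend: list[dict[str, Any]]
    region_within: list[dict[str, Any]]
    contribution_rates: list[dict[str, Any]]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisReport":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))

    def write_csv_tables(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("densities", "percent_changes", "extremes",
                     "theil_trend", "region_within", "contribution_rates"):
            rows = getattr(self, name)
            if rows:
                path = directory / f"{name}.csv"
                pd.DataFrame(rows).to_csv(path, index=False)
                written.append(path)
        return written


def _density_records(table: indicators.DensityTable) -> list[dict[str, Any]]:
    frame = table.frame.copy()
    frame["per_km2"] = frame["per_km2"].astype(object).where(frame["per_km2"].notna(), None)
    return frame.to_dict(orient="records")


def run_report(panel: ResourcePanel, settings: ReportSettings | None = None) -> AnalysisReport:
    """Run the full analysis skeleton over a panel.

    Stages, in order: density table, start→end percent changes, per-year
    extremes, per-year Theil decompositions with contribution rates.  A
    density-flagged panel (no raw counts) keeps the density-level stages and
    skips the Theil stages with an explicit warning.
    """
    settings = settings or ReportSettings()
    warnings_out: list[str] = []
    metadata = {
        "provenance": panel.provenance,
        "years": list(panel.years),
        "n_provinces": len(panel.provinces),
        # JSON-normalized (tuples to lists) so reports round-trip losslessly
        "settings": json.loads(json.dumps(dataclasses.asdict(settings))),
        "values_are_densities": panel.values_are_densities,
    }

    if panel.values_are_densities:
        table = indicators.DensityTable.from_density_panel(panel)
    else:
        table = indicators.density_table(panel)
    densities = _density_records(table)

    percent_changes: list[dict[str, Any]] = []
    years = panel.years
    if len(years) >= 2 and not panel.values_are_densities:
        pct = indicators.percent_change_table(
            table, years[0], years[-1], mode=settings.percent_mode
        )
        percent_changes = pct.to_dict(orient="records")

    extremes_rows: list[dict[str, Any]] = []
    provinces = [p for p in panel.provinces if p != indicators.TOTAL_LABEL]
    for year in years:
        for resource in settings.resources:
            for perspective in settings.extremes_perspectives:
                try:
                    summary = indicators.extremes(table, resource, perspective, year)
                except (ValueError, KeyError):
                    continue
                if pd.isna(summary.min_value):
                    continue
                extremes_rows.append(dataclasses.asdict(summary))
    if len(provinces) < 2:
        extremes_rows = []
        warnings_out.append("extremes skipped: fewer than 2 provinces")

    trend_rows: list[dict[str, Any]] = []
    region_rows: list[dict[str, Any]] = []
    rate_rows: list[dict[str, Any]] = []
    if panel.values_are_densities:
        warnings_out.append(
            "Theil stages skipped: panel stores printed densities, not counts"
        )
    elif all(rec.region is None for rec in panel.records):
        warnings_out.append("Theil stages skipped: no region labels on records")
    else:
        for resource in settings.resources:
            try:
                series = theil.theil_trend(panel, resource, zero_policy=settings.zero_policy)
            except (ValueError, theil.ZeroShareError) as exc:
                warnings_out.append(f"Theil trend skipped for {resource}: {exc}")
                continue
            trend_rows += theil.trend_frame(series).to_dict(orient="records")
            region_rows += theil.region_within_frame(series).to_dict(orient="records")
            rate_rows += theil.contribution_frame(series).to_dict(orient="records")

    report = AnalysisReport(
        metadata=metadata,
        densities=densities,
        percent_changes=percent_changes,
        extremes=extremes_rows,
        theil_trend=trend_rows,
        region_within=region_rows,
        contribution_rates=rate_rows,
        warnings=warnings_out,
    )
    for message in warnings_out:
        log.warning(message)
    return report


def plot_report(report: AnalysisReport, directory: str | Path) -> list[Path]:
    """Render the three standard figures: total-Theil trends per resource,
    per-region within-group Theil, and contribution rates over time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    trend = pd.DataFrame(report.theil_trend)
    if not trend.empty:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        totals = trend[trend["component"] == "total"]
        for resource, sub in totals.groupby("resource"):
            ax.plot(sub["year"], sub["value"], marker="o", label=resource)
        ax.set_xlabel("year")
        ax.set_ylabel("Theil index (nats)")
        ax.set_title("Total Theil index by resource")
        ax.legend(fontsize=8)
        path = directory / "theil_total_trend.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    region = pd.DataFrame(report.region_within)
    if not region.empty:
        resources = sorted(region["resource"].unique())
        fig, axes = plt.subplots(1, len(resources), figsize=(4 * len(resources), 3.5), squeeze=False)
        for ax, resource in zip(axes[0], resources):
            sub = region[region["resource"] == resource]
            for reg, rsub in sub.groupby("region"):
                ax.plot(rsub["year"], rsub["T_within_region"], marker="o", label=reg)
            ax.set_title(resource, fontsize=9)
            ax.set_xlabel("year")
        axes[0][0].set_ylabel("within-region Theil")
        axes[0][-1].legend(fontsize=8)
        path = directory / "theil_by_region.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    rates = pd.DataFrame(report.contribution_rates)
    if not rates.empty:
        resources = sorted(rates["resource"].unique())
        fig, axes = plt.subplots(1, len(resources), figsize=(4 * len(resources), 3.5), squeeze=False)
        for ax, resource in zip(axes[0], resources):
            sub = rates[rates["resource"] == resource]
            for comp, csub in sub.groupby("component"):
                ax.plot(csub["year"], csub["contribution_rate"], marker="o", label=comp)
            ax.set_title(resource, fontsize=9)
            ax.set_xlabel("year")
        axes[0][0].set_ylabel("contribution rate")
        axes[0][-1].legend(fontsize=8)
        path = directory / "contribution_rates.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    return written
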