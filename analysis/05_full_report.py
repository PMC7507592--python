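#!/usr/bin/env python
"""One-shot report over the synthetic panel, with figures.

Runs the full pipeline (densities → percent changes → extremes → Theil
trends → contribution rates) and writes results/report.json, CSV
projections under results/report_tables/, and the three standard figures
under results/figures/.
"""

from pathlib import Path

from healtheil.data_model import read_panel
from healtheil.report import plot_report, run_report
from healtheil.synthetic_data import SimulationConfig, simulate_panel

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    panel_csv = OUT / "synthetic_panel.csv"
    panel = (
        read_panel(panel_csv)
        if panel_csv.exists()
        else simulate_panel(SimulationConfig(seed=20130))
    )
    report = run_report(panel)
    report.to_json(OUT / "report.json")
    tables = report.write_csv_tables(OUT / "report_tables")
    figures = plot_report(report, OUT / "figures")
    print(f"report: {OUT / 'report.json'}")
    print(f"tables: {[p.name for p in tables]}")
    print(f"figures: {[p.name for p in figures]}")
    if report.warnings:
        print("warnings:", report.warnings)


if __name__ == "__main__":
    main()
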