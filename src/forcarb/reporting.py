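"""Result tables: stocks, densities, proportions and carbon values per group.

A report row carries area, carbon stock, its share of the total, carbon
density, the value under the market and shadow price schemes, their mean,
and the mean value per hectare.  Rows are sorted by descending carbon; a
grand-total row closes the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import pandas as pd

from .estimators import StockTable
from .valuation import PriceScheme, average_valuation, monetize


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class ReportTable:
    dimension: str
    rows: pd.DataFrame  # sorted descending by carbon_tC
    grand_total: pd.Series

    def to_frame(self) -> pd.DataFrame:
        total = self.grand_total.to_frame().T
        total.index = pd.Index(["total"], name=self.rows.index.name)
        return pd.concat([self.rows, total])


REPORT_COLUMNS = [
    "area_hm2",
    "carbon_tC",
    "proportion_pct",
    "density_tC_per_hm2",
    "value_market_wan_cny",
    "value_optimal_wan_cny",
    "value_mean_wan_cny",
    "value_mean_cny_per_hm2",
]


def build_report(
    stocks: StockTable,
    market: PriceScheme,
    optimal: PriceScheme,
    by: str = "vegetation_type",
) -> ReportTable:
    """Assemble a per-group stock/value report along one dimension."""
    groups = stocks.by(by)
    if groups.empty:
        raise ReportError(f"no records to report along {by!r}")
    vm = monetize(groups, market)
    vo = monetize(groups, optimal)
    vmean = average_valuation(vm, vo)

    rows = groups.copy()
    total_carbon = rows["carbon_tC"].sum()
    rows["proportion_pct"] = (
        100.0 * rows["carbon_tC"] / total_carbon if total_carbon > 0 else 0.0
    )
    rows["value_market_wan_cny"] = vm["value_wan_cny"]
    rows["value_optimal_wan_cny"] = vo["value_wan_cny"]
    rows["value_mean_wan_cny"] = vmean["value_wan_cny"]
    rows["value_mean_cny_per_hm2"] = vmean["value_cny_per_hm2"]
    rows = rows[REPORT_COLUMNS].sort_values("carbon_tC", ascending=False)

    total = rows[
        [
            "area_hm2",
            "carbon_tC",
            "proportion_pct",
            "value_market_wan_cny",
            "value_optimal_wan_cny",
            "value_mean_wan_cny",
        ]
    ].sum()
    total["density_tC_per_hm2"] = (
        total["carbon_tC"] / total["area_hm2"] if total["area_hm2"] > 0 else 0.0
    )
    total["value_mean_cny_per_hm2"] = (
        total["value_mean_wan_cny"] * 1e4 / total["area_hm2"]
        if total["area_hm2"] > 0
        else 0.0
    )
    return ReportTable(dimension=by, rows=rows, grand_total=total[REPORT_COLUMNS])


@dataclass(frozen=True)
class RankedGroup:
    group: str
    value: float
    tied: bool


def ranking(report: ReportTable, column: str = "carbon_tC") -> list[RankedGroup]:
    """Groups in strictly descending order of ``column``; ties flagged.

    Tie-breaking is lexicographic on the group name.
    """
    if report.rows.empty:
        raise ReportError("cannot rank an empty report")
    if column not in report.rows.columns:
        raise ReportError(f"unknown column {column!r}")
    ordered = report.rows[column].reset_index()
    key = ordered.columns[0]
    ordered = ordered.sort_values([column, key], ascending=[False, True])
    values = ordered[column].to_list()
    tied = [values.count(v) > 1 for v in values]
    return [
        RankedGroup(group=str(g), value=float(v), tied=t)
        for g, v, t in zip(ordered[key], values, tied)
    ]


def to_markdown(report: ReportTable, ndigits: int = 2) -> str:
    frame = report.to_frame().round(ndigits)
    key = frame.index.name or "group"
    header = [key, *frame.columns]
    lines = [
        "| " + " | ".join(header) + " |",
        "|" + "|".join("---" for _ in header) + "|",
    ]
    for idx, row in frame.iterrows():
        cells = [str(idx)] + [f"{v:.{ndigits}f}" for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def to_csv(report: ReportTable, sink: str | IO[str]) -> None:
    report.to_frame().to_csv(sink)
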