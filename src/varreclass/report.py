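"""Rendering of rate tables and the JSON run summary.

Percentages are computed at full precision upstream and rounded only here:
the per-term "percentage reclassified" column always shows two decimals
(its values sit well under 3%), while the share columns show one decimal at
or above 1% and two decimals below it — the conventional precision for
archive-audit tables.
"""

from __future__ import annotations

import csv
import io
import json
from typing import Any

from .lp import LPConfidenceEstimate
from .strata import StratumComparison
from .transitions import DirectionSummary, RateTable


def fmt_pct_2dp(frac: float) -> str:
    return f"{100 * frac:.2f}%"


def fmt_share(frac: float) -> str:
    pct = 100 * frac
    return f"{pct:.1f}%" if pct >= 1 else f"{pct:.2f}%"


def render_rate_table_text(table: RateTable) -> str:
    """Aligned plain-text rate table: five starting-term blocks, transition
    cells in the fixed order P, LP, VUS, LB, B."""
    lines = []
    header = (
        f"{'Starting classification (n)':<34}{'Reclassified':<18}"
        f"{'Transition (n)':<20}{'% of group':>12}{'% of all':>10}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    for row in table.rows:
        start_label = f"{row.term.label} ({row.start_total:,})"
        reclass = f"{fmt_pct_2dp(row.frac_reclassified)} ({row.n_reclassified})"
        if not row.cells:
            lines.append(f"{start_label:<34}{reclass:<18}{'-':<20}{'-':>12}{'-':>10}")
            continue
        first = True
        for cell in row.cells:
            lines.append(
                f"{start_label if first else '':<34}{reclass if first else '':<18}"
                f"{f'{cell.from_term} -> {cell.to_term} ({cell.count})':<20}"
                f"{fmt_share(cell.frac_of_group):>12}{fmt_share(cell.frac_of_all):>10}"
            )
            first = False
    lines.append("-" * len(header))
    lines.append(
        f"Total: {table.total_classifications:,} classifications, "
        f"{table.total_events:,} reclassified ({fmt_pct_2dp(table.overall_rate)})"
    )
    return "\n".join(lines) + "\n"


def render_rate_table_tsv(table: RateTable) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["StartTerm", "StartTotal", "PctReclassified", "NReclassified",
                "FromTerm", "ToTerm", "Count", "PctOfGroup", "PctOfAll"])
    for row in table.rows:
        if not row.cells:
            w.writerow([row.term, row.start_total, fmt_pct_2dp(row.frac_reclassified),
                        row.n_reclassified, "", "", "", "", ""])
            continue
        for cell in row.cells:
            w.writerow([row.term, row.start_total, fmt_pct_2dp(row.frac_reclassified),
                        row.n_reclassified, cell.from_term, cell.to_term, cell.count,
                        fmt_share(cell.frac_of_group), fmt_share(cell.frac_of_all)])
    return buf.getvalue()


def rate_table_dict(table: RateTable) -> dict[str, Any]:
    """Full-precision fractions, for the JSON run summary."""
    return {
        "total_classifications": table.total_classifications,
        "total_events": table.total_events,
        "overall_rate": table.overall_rate,
        "rows": [
            {
                "term": row.term.label,
                "start_total": row.start_total,
                "n_reclassified": row.n_reclassified,
                "frac_reclassified": row.frac_reclassified,
                "cells": [
                    {
                        "from": c.from_term.label, "to": c.to_term.label,
                        "count": c.count,
                        "frac_of_group": c.frac_of_group,
                        "frac_of_all": c.frac_of_all,
                    }
                    for c in row.cells
                ],
            }
            for row in table.rows
        ],
    }


def direction_dict(ds: DirectionSummary) -> dict[str, Any]:
    return {
        "more_certain": ds.more_certain,
        "less_certain": ds.less_certain,
        "opposing": ds.opposing,
        "total": ds.total,
        "frac_more_certain": ds.fraction("more_certain"),
        "frac_less_certain": ds.fraction("less_certain"),
        "frac_opposing": ds.fraction("opposing"),
    }


def render_run_report(
    table: RateTable,
    directions: DirectionSummary,
    lp_estimate: LPConfidenceEstimate | None,
    comparisons: list[StratumComparison],
) -> str:
    """Human-readable run report (a pure function of the summary data)."""
    out = [render_rate_table_text(table), ""]
    if directions.total:
        out.append("Certainty direction of reclassifications:")
        out.append(
            f"  more certain: {directions.more_certain} "
            f"({fmt_share(directions.fraction('more_certain'))})"
        )
        out.append(
            f"  less certain: {directions.less_certain} "
            f"({fmt_share(directions.fraction('less_certain'))})"
        )
        out.append(
            f"  opposing:     {directions.opposing} "
            f"({fmt_share(directions.fraction('opposing'))})"
        )
        out.append("")
    if lp_estimate is not None:
        e = lp_estimate
        out.append("LP confidence estimators:")
        out.append(
            f"  definitive (P vs B):        {fmt_share(e.rate_definitive)} "
            f"({e.n_to_p}/{e.n_to_p + e.n_to_b})"
        )
        out.append(
            f"  definitive (P vs LB+B):     {fmt_share(e.rate_definitive_lb)} "
            f"({e.n_to_p}/{e.n_to_p + e.n_to_lb + e.n_to_b})"
        )
        out.append(
            f"  extrapolated (worst case):  {fmt_share(e.rate_extrapolated)} "
            f"(({e.n_to_p} + {e.extrap_up})/{e.n_lp_events})"
        )
        out.append(
            f"  VUS fates: {fmt_share(e.vus_down_rate)} down / "
            f"{fmt_share(e.vus_up_rate)} up"
        )
        out.append("")
    for c in comparisons:
        if not c.computable:
            out.append(f"Comparison {c.stratum_a} vs {c.stratum_b}: not computable ({c.reason})")
            continue
        out.append(
            f"Comparison {c.stratum_a} vs {c.stratum_b}: "
            f"{fmt_share(c.fraction_a)} ({c.upgraded_a}/{c.total_a}) vs "
            f"{fmt_share(c.fraction_b)} ({c.upgraded_b}/{c.total_b}), "
            f"Fisher two-sided p = {c.p_value:.3f}"
        )
    return "\n".join(out) + "\n"


def write_json(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
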