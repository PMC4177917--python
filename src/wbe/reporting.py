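"""Rendering of load/removal results into report tables.

Display conventions follow how WWTP monitoring campaigns print results:
mean +/- sd concentrations as integers (ng/L), daily loads to three
significant figures (mg/d), percent loss to the nearest integer with a
minus sign marking an in-plant increase, "<" marking an influent entirely
below the LOQ, and "na" where a quantity is not applicable. Full-precision
values always remain available on the underlying objects; rounding happens
only here.
"""

from __future__ import annotations

import csv
import math
from io import StringIO
from typing import Mapping, Sequence

from .loads import BELOW_LOQ_INFLUENT, LoadSummary, RemovalResult

__all__ = [
    "round_sig",
    "format_mean_sd",
    "format_load",
    "format_percent_loss",
    "render_table2",
    "render_table3",
]

NA = "na"


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def format_mean_sd(summary: LoadSummary | None) -> str:
    """"433±472"-style mean concentration above LOQ; bare mean when n<2."""
    if summary is None or summary.mean_conc_above_loq_ng_per_l is None:
        return "<LOQ"
    mean = round(summary.mean_conc_above_loq_ng_per_l)
    if summary.sd_conc_above_loq is None:
        return f"{mean:d}"
    return f"{mean:d}±{round(summary.sd_conc_above_loq):d}"


def format_load(summary: LoadSummary | None) -> str:
    if summary is None:
        return NA
    return format(round_sig(summary.daily_load_mg_per_d, 3), "g")


def format_percent_loss(removal: RemovalResult | None) -> str:
    """Integer percent; "−94%" means a 94% increase inlet→outlet."""
    if removal is None:
        return NA
    if removal.percent_loss == BELOW_LOQ_INFLUENT:
        return "<"
    if removal.effluent_load_mg_d == 0 and removal.influent_load_mg_d == 0:
        return NA
    return f"{round(removal.percent_loss):d}%"


def render_table2(
    load_summaries: Sequence[LoadSummary],
    removals: Sequence[RemovalResult],
) -> str:
    """Render influent/effluent statistics and percent loss as CSV text.

    One row per analyte: mean+/-sd above LOQ for each stream, daily loads,
    and the signed percent loss. Requires influent and effluent summaries
    (an analyte measured in only one stream renders "na" in the other).
    """
    streams = {s.stream for s in load_summaries}
    if not streams <= {"influent", "effluent"}:
        raise ValueError(f"expected influent/effluent summaries, got {streams}")
    by_analyte: dict[str, dict[str, LoadSummary]] = {}
    for s in load_summaries:
        by_analyte.setdefault(s.analyte.name, {})[s.stream] = s
    removal_by_analyte: Mapping[str, RemovalResult] = {
        r.analyte.name: r for r in removals
    }
    buf = StringIO()
    writer = csv.writer(buf)
    writer.writerow(
        [
            "analyte",
            "influent_mean_sd_ng_l",
            "influent_load_mg_d",
            "effluent_mean_sd_ng_l",
            "effluent_load_mg_d",
            "percent_loss",
        ]
    )
    for name in sorted(by_analyte):
        inf = by_analyte[name].get("influent")
        eff = by_analyte[name].get("effluent")
        writer.writerow(
            [
                name,
                format_mean_sd(inf),
                format_load(inf),
                format_mean_sd(eff),
                format_load(eff),
                format_percent_loss(removal_by_analyte.get(name)),
            ]
        )
    return buf.getvalue()


def render_table3(comparison_rows: Sequence[Mapping]) -> str:
    """Render predicted-vs-measured load comparisons as CSV text."""
    buf = StringIO()
    writer = csv.writer(buf)
    writer.writerow(
        ["analyte", "predicted_excreted_mg_d", "measured_load_mg_d", "ratio", "direction"]
    )
    for row in comparison_rows:
        measured = row["measured_load_mg_d"]
        ratio = row["ratio"]
        writer.writerow(
            [
                row["analyte"],
                format(round_sig(row["predicted_excreted_mg_d"], 3), "g"),
                NA if measured is None else format(round_sig(measured, 3), "g"),
                NA if ratio is None else format(round_sig(ratio, 3), "g"),
                row["direction"],
            ]
        )
    return buf.getvalue()
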