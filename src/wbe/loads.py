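"""Daily mass loads, removal mass balance and per-capita normalisation.

The central bookkeeping of the pipeline: hourly concentrations (ng/L) times
hourly flows (m3/h) give hourly loads (mg/h); the 24-h sum is the daily
load (mg/d). Left-censored hours contribute a value chosen by an explicit
censoring policy — zero by default, which makes daily loads conservative
lower bounds. Removal across a WWTP is the signed percent change in daily
load between influent and effluent sampled over the same day; negative
values mean the effluent carried more mass than the influent (desorption or
deconjugation inside the works).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from statistics import mean, stdev
from typing import Literal, Sequence

from .core_data import AnalyteSpec, FlowSeries, SampleSeries
from .units import UG_PER_MG, conc_flow_to_load_mg

__all__ = [
    "LoadSummary",
    "RemovalResult",
    "BELOW_LOQ_INFLUENT",
    "CensorPolicy",
    "hourly_load",
    "daily_load",
    "percent_loss",
    "per_capita_load",
    "detection_frequency",
]

CensorPolicy = Literal["zero", "half_loq", "loq"]
_POLICY_FACTORS = {"zero": 0.0, "half_loq": 0.5, "loq": 1.0}

#: sentinel for a removal that cannot be quantified because the influent was
#: entirely below the LOQ while the effluent was not (rendered "<")
BELOW_LOQ_INFLUENT = "below-loq-influent"


@dataclass
class LoadSummary:
    """Daily load and concentration statistics for one analyte and stream."""

    analyte: AnalyteSpec
    stream: str
    daily_load_mg_per_d: float
    max_hourly_load_mg_per_h: float
    max_hourly_load_at: datetime | None
    mean_conc_above_loq_ng_per_l: float | None
    sd_conc_above_loq: float | None
    n_above_loq: int
    n_total: int
    per_capita_ug_per_cap_per_d: float | None = None

    def __post_init__(self) -> None:
        if self.n_above_loq > self.n_total:
            raise ValueError("n_above_loq cannot exceed n_total")
        if self.daily_load_mg_per_d < 0:
            raise ValueError("daily load cannot be negative")


@dataclass
class RemovalResult:
    """Signed percent loss of one analyte between influent and effluent."""

    analyte: AnalyteSpec
    influent_load_mg_d: float
    effluent_load_mg_d: float
    percent_loss: float | str  # signed %, or BELOW_LOQ_INFLUENT sentinel


def hourly_load(conc_ng_per_l: float, flow_m3_per_h: float) -> float:
    """Hourly mass load (mg/h) from concentration and flow.

    ng/L x m3/h yields ug/h; dividing by 1000 gives mg/h.
    """
    if conc_ng_per_l < 0 or flow_m3_per_h < 0:
        raise ValueError("concentration and flow must be nonnegative")
    return conc_flow_to_load_mg(conc_ng_per_l, flow_m3_per_h)


def _substituted_conc(
    measurement_censored: bool,
    conc: float | None,
    loq: float,
    policy: CensorPolicy,
) -> float:
    if not measurement_censored:
        return conc  # type: ignore[return-value]
    try:
        return _POLICY_FACTORS[policy] * loq
    except KeyError:
        raise ValueError(f"unknown censor policy {policy!r}") from None


def daily_load(
    series: SampleSeries,
    flows: FlowSeries,
    censor_policy: CensorPolicy = "zero",
    *,
    population: int | None = None,
    allow_gaps: bool = False,
) -> LoadSummary:
    """Aggregate 24 aligned hourly measurements and flows into a daily load.

    Censored hours are substituted per ``censor_policy`` (default: zero).
    The mean and standard deviation of concentration are computed over the
    uncensored samples only, matching how composite-sampling campaigns
    report "mean for samples >LOQ". With ``allow_gaps`` the partial-day sum
    is renormalised to 24 h by the covered-hour fraction.

    Parameters
    ----------
    population
        If given, the per-capita load (ug/cap/d) is filled in.
    """
    n = len(series.measurements)
    n_flows = len(flows.records)
    if n != n_flows:
        raise ValueError(
            f"{series.site_id}/{series.analyte.name}: {n} measurements but "
            f"{n_flows} flow records; series must be aligned"
        )
    if n == 0:
        raise ValueError("empty series")
    if n < 24 and not allow_gaps:
        raise ValueError(
            f"{series.site_id}/{series.analyte.name}: only {n} of 24 hours "
            "present; pass allow_gaps=True to renormalise"
        )
    for m, (ft, _) in zip(series.measurements, flows.records):
        if m.timestamp != ft:
            raise ValueError(
                f"sample at {m.timestamp} does not align with flow at {ft}"
            )

    loq = series.analyte.loq_ng_per_l
    total = 0.0
    max_load = 0.0
    max_at: datetime | None = None
    for m, (_, flow) in zip(series.measurements, flows.records):
        conc = _substituted_conc(m.censored, m.concentration_ng_per_l, loq, censor_policy)
        load = hourly_load(conc, flow)
        total += load
        if max_at is None or load > max_load:
            max_load, max_at = load, m.timestamp
    if allow_gaps and n < 24:
        total *= 24 / n

    above = [m.concentration_ng_per_l for m in series.measurements if not m.censored]
    summary = LoadSummary(
        analyte=series.analyte,
        stream=series.matrix,
        daily_load_mg_per_d=total,
        max_hourly_load_mg_per_h=max_load,
        max_hourly_load_at=max_at,
        mean_conc_above_loq_ng_per_l=mean(above) if above else None,
        sd_conc_above_loq=stdev(above) if len(above) >= 2 else None,
        n_above_loq=len(above),
        n_total=n,
    )
    if population is not None:
        summary.per_capita_ug_per_cap_per_d = per_capita_load(total, population)
    return summary


def percent_loss(influent: LoadSummary, effluent: LoadSummary) -> RemovalResult:
    """Signed percent loss of daily load across the works.

    100 x (influent - effluent) / influent. When the influent was entirely
    censored (zero load) but the effluent was not, removal is unquantifiable
    and the ``BELOW_LOQ_INFLUENT`` sentinel is returned.
    """
    if influent.analyte.name != effluent.analyte.name:
        raise ValueError(
            f"analyte mismatch: {influent.analyte.name} vs {effluent.analyte.name}"
        )
    li, le = influent.daily_load_mg_per_d, effluent.daily_load_mg_per_d
    if li == 0:
        loss: float | str = BELOW_LOQ_INFLUENT if le > 0 else 0.0
    else:
        loss = 100.0 * (li - le) / li
    return RemovalResult(influent.analyte, li, le, loss)


def per_capita_load(daily_load_mg_d: float, population: int) -> float:
    """Per-capita daily load, ug/cap/d."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return daily_load_mg_d * UG_PER_MG / population


def detection_frequency(series: SampleSeries | Sequence[bool]) -> float:
    """Fraction of samples above the LOQ."""
    if isinstance(series, SampleSeries):
        n_total, n_above = series.n_total, series.n_above_loq
    else:
        n_total, n_above = len(series), sum(series)
    if n_total == 0:
        raise ValueError("empty series has no detection frequency")
    return n_above / n_total
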