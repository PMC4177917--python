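"""Catchment-scale river analysis.

Per-site daily loads from grab samples, per-capita usage normalised by the
upstream population, ordinary-least-squares regression of load on upstream
population (the check that a conservative analyte accumulates linearly with
the contributing population), and summaries comparing sampling periods
(pandemic / late-pandemic / inter-pandemic).

A single grab sample is treated as the day's representative concentration;
its daily load is concentration times the daily mean river flow.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy import stats

from .core_data import RiverSample, RiverSite
from .loads import per_capita_load
from .units import conc_flow_to_load_mg

__all__ = [
    "SiteLoad",
    "PeriodSummary",
    "RegressionResult",
    "site_daily_load",
    "population_load_regression",
    "period_summary",
]


@dataclass
class SiteLoad:
    """Daily load of one analyte at one river site on one date."""

    site_id: str
    date: datetime
    analyte_name: str
    concentration_ng_per_l: float | None
    censored: bool
    daily_load_mg_d: float
    per_capita_ug_cap_d: float
    upstream_population: int


@dataclass
class PeriodSummary:
    """Detection and concentration statistics for one labelled period."""

    period: str
    detection_fraction: dict[str, float]
    mean_conc_ng_per_l: dict[str, float | None]
    max_conc_ng_per_l: dict[str, float | None]
    mean_analytes_detected_per_site: float
    sd_analytes_detected_per_site: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_sites: int


def site_daily_load(
    sample: RiverSample, site: RiverSite
) -> SiteLoad:
    """Daily load and per-capita usage implied by one grab sample.

    Censored samples carry zero load (the conservative default policy).
    """
    if not sample.censored and site.flow_m3_per_d <= 0:
        raise ValueError(f"{site.site_id}: flow must be > 0 for an uncensored sample")
    if sample.censored:
        load = 0.0
    else:
        load = conc_flow_to_load_mg(sample.concentration_ng_per_l, site.flow_m3_per_d)
    return SiteLoad(
        site_id=site.site_id,
        date=sample.date,
        analyte_name=sample.analyte.name,
        concentration_ng_per_l=sample.concentration_ng_per_l,
        censored=sample.censored,
        daily_load_mg_d=load,
        per_capita_ug_cap_d=per_capita_load(load, site.upstream_population),
        upstream_population=site.upstream_population,
    )


def population_load_regression(
    site_loads: list[SiteLoad],
) -> RegressionResult | None:
    """OLS of daily load (mg/d) on upstream population, uncensored sites only.

    Returns None when fewer than 3 uncensored sites are available — no
    meaningful fit exists.
    """
    points = [
        (s.upstream_population, s.daily_load_mg_d) for s in site_loads if not s.censored
    ]
    if len(points) < 3:
        return None
    x = np.array([p for p, _ in points], dtype=float)
    y = np.array([l for _, l in points], dtype=float)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.rvalue**2,
        n_sites=len(points),
    )


def period_summary(
    sites: list[RiverSite],
    period_of: dict[datetime, str] | None = None,
    *,
    analyte_subset: list[str] | None = None,
) -> list[PeriodSummary]:
    """Per-period detection fractions, concentration statistics and
    analytes-detected-per-site counts.

    ``period_of`` maps sample dates (date component) to period labels; when
    omitted, every sample falls into a single "all" period. Per-site
    detection counts include sites where nothing was detected (zeros count
    toward the mean), mirroring how a monitoring campaign reports "mean
    analytes found per site".
    """

    def label(ts: datetime) -> str:
        if period_of is None:
            return "all"
        key = datetime(ts.year, ts.month, ts.day)
        try:
            return period_of[key]
        except KeyError:
            raise ValueError(f"sample date {key.date()} has no period label") from None

    # period -> analyte -> [(censored, conc)]
    per_period: dict[str, dict[str, list[tuple[bool, float | None]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    # period -> site -> set of detected analytes
    detected_per_site: dict[str, dict[str, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    site_ids: dict[str, set[str]] = defaultdict(set)
    for site in sites:
        for sample in site.samples:
            name = sample.analyte.name
            if analyte_subset is not None and name not in analyte_subset:
                continue
            period = label(sample.date)
            per_period[period][name].append(
                (sample.censored, sample.concentration_ng_per_l)
            )
            site_ids[period].add(site.site_id)
            if not sample.censored:
                detected_per_site[period][site.site_id].add(name)

    summaries = []
    for period in sorted(per_period):
        detection: dict[str, float] = {}
        mean_conc: dict[str, float | None] = {}
        max_conc: dict[str, float | None] = {}
        for name, obs in sorted(per_period[period].items()):
            if not obs:
                raise ValueError(f"period {period!r}/{name}: no samples")
            above = [c for censored, c in obs if not censored]
            detection[name] = len(above) / len(obs)
            mean_conc[name] = float(np.mean(above)) if above else None
            max_conc[name] = float(np.max(above)) if above else None
        counts = [
            len(detected_per_site[period].get(site_id, ()))
            for site_id in sorted(site_ids[period])
        ]
        summaries.append(
            PeriodSummary(
                period=period,
                detection_fraction=detection,
                mean_conc_ng_per_l=mean_conc,
                max_conc_ng_per_l=max_conc,
                mean_analytes_detected_per_site=float(np.mean(counts)),
                sd_analytes_detected_per_site=(
                    float(np.std(counts, ddof=1)) if len(counts) >= 2 else 0.0
                ),
            )
        )
    return summaries
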