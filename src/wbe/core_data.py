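"""Domain types and tabular I/O shared by every analysis stage.

The package models three water matrices — WWTP influent, WWTP effluent and
river water — each sampled for a panel of pharmaceuticals (antibiotics,
decongestants and the antiviral metabolite oseltamivir carboxylate).
Concentrations below an analyte's limit of quantification (LOQ) are
*left-censored*: the laboratory reports only "<LOQ". Censoring is stored as
a flag on each measurement and never silently replaced by a number; any
substitution (zero, LOQ/2, LOQ) happens downstream under a named policy.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "AnalyteSpec",
    "Measurement",
    "SampleSeries",
    "FlowSeries",
    "CatchmentConfig",
    "RiverSite",
    "RiverSample",
    "CENSORED_TOKEN",
    "load_analyte_table",
    "analyte_by_name",
    "read_sample_series",
    "write_sample_series",
    "read_flow_series",
    "validate_catchment",
]

CENSORED_TOKEN = "<LOQ"

Matrix = Literal["influent", "effluent", "river"]
_MATRICES = ("influent", "effluent", "river")


@dataclass(frozen=True)
class AnalyteSpec:
    """Dosing, pharmacokinetic and quantification metadata for one drug.

    Parameters
    ----------
    adq_g
        Average Daily Quantity in grams — an England-specific measure of
        prescribing volume, close to the WHO defined daily dose.
    excreted_fraction
        Fraction of the parent dose excreted to sewer in bioactive form
        (the pharmacokinetic factor E), in (0, 1].
    loq_ng_per_l
        Limit of quantification of the analytical method, ng/L.
    """

    name: str
    atc_code: str
    drug_class: str
    adq_g: float
    excreted_fraction: float
    loq_ng_per_l: float

    def __post_init__(self) -> None:
        if not self.adq_g > 0:
            raise ValueError(f"{self.name}: adq_g must be > 0, got {self.adq_g}")
        if not 0 < self.excreted_fraction <= 1:
            raise ValueError(
                f"{self.name}: excreted_fraction must be in (0, 1], "
                f"got {self.excreted_fraction}"
            )
        if not self.loq_ng_per_l > 0:
            raise ValueError(
                f"{self.name}: loq_ng_per_l must be > 0, got {self.loq_ng_per_l}"
            )


@dataclass(frozen=True)
class Measurement:
    """One timestamped concentration, possibly left-censored.

    A censored measurement carries ``concentration_ng_per_l=None``; the
    numeric value is unknown, only that it fell below the LOQ. Hourly
    samples represent the preceding hour (a sample stamped 18:00 covers
    17:00-18:00).
    """

    timestamp: datetime
    concentration_ng_per_l: float | None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.censored and self.concentration_ng_per_l is not None:
            raise ValueError("censored measurement must not carry a numeric value")
        if not self.censored:
            if self.concentration_ng_per_l is None:
                raise ValueError("uncensored measurement requires a concentration")
            if self.concentration_ng_per_l < 0:
                raise ValueError(
                    f"concentration must be nonnegative, got "
                    f"{self.concentration_ng_per_l}"
                )


@dataclass
class SampleSeries:
    """Ordered measurements of one analyte in one matrix at one site."""

    site_id: str
    matrix: Matrix
    analyte: AnalyteSpec
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix not in _MATRICES:
            raise ValueError(f"matrix must be one of {_MATRICES}, got {self.matrix!r}")
        times = [m.timestamp for m in self.measurements]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.site_id}/{self.analyte.name}: timestamps must be strictly increasing")

    @property
    def n_total(self) -> int:
        return len(self.measurements)

    @property
    def n_above_loq(self) -> int:
        return sum(not m.censored for m in self.measurements)


@dataclass
class FlowSeries:
    """Hourly flow records (m3/h) or a single daily flow (m3/d) for a site."""

    site_id: str
    records: list[tuple[datetime, float]] = field(default_factory=list)
    daily_flow_m3_per_d: float | None = None

    def __post_init__(self) -> None:
        if self.daily_flow_m3_per_d is not None and self.daily_flow_m3_per_d < 0:
            raise ValueError("daily flow must be nonnegative")
        times = [t for t, _ in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.site_id}: flow timestamps must be strictly increasing")
        if any(q < 0 for _, q in self.records):
            raise ValueError(f"{self.site_id}: flows must be nonnegative")

    @property
    def flows_m3_per_h(self) -> list[float]:
        return [q for _, q in self.records]

    def total_m3_per_d(self) -> float:
        if self.records:
            return sum(q for _, q in self.records)
        if self.daily_flow_m3_per_d is None:
            raise ValueError(f"{self.site_id}: no flow data")
        return self.daily_flow_m3_per_d


@dataclass
class CatchmentConfig:
    """A WWTP catchment: who contributes to the sewer and how much water.

    ``correction_factor`` (F) maps prescription statistics reported for a
    Primary Care Trust (PCT) population onto the subset actually served by
    this WWTP; F = 1 means the populations coincide (always the case for
    national statistics).
    """

    wwtp_id: str
    population_served: int
    wastewater_per_capita_l_per_d: float = 230.0
    pct_population: int | None = None
    correction_factor: float | None = None

    def daily_wastewater_l(self) -> float:
        """Total catchment wastewater volume, L/d (P x L)."""
        return self.population_served * self.wastewater_per_capita_l_per_d


@dataclass(frozen=True)
class RiverSample:
    """One grab sample: date, analyte, concentration or censored."""

    date: datetime
    analyte: AnalyteSpec
    concentration_ng_per_l: float | None
    censored: bool = False


@dataclass
class RiverSite:
    """River sampling location with its upstream population and flow."""

    site_id: str
    name: str
    upstream_population: int
    flow_m3_per_d: float
    samples: list[RiverSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.upstream_population <= 0:
            raise ValueError(f"{self.site_id}: upstream_population must be > 0")
        if self.flow_m3_per_d < 0:
            raise ValueError(f"{self.site_id}: flow must be nonnegative")


# ---------------------------------------------------------------------------
# packaged analyte panel
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "atc_code",
    "name",
    "drug_class",
    "adq_g",
    "excreted_fraction",
    "loq_ng_per_l",
)


def load_analyte_table() -> list[AnalyteSpec]:
    """Load the packaged 15-analyte panel (11 antibiotics, 3 decongestants,
    oseltamivir carboxylate) with ADQ, excreted fraction and LOQ."""
    ref = importlib.resources.files("wbe").joinpath("data/analytes.csv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_REQUIRED_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"analyte table is corrupt: missing field(s) {sorted(missing)}"
            )
        specs = []
        for row in reader:
            for f in _REQUIRED_FIELDS:
                if not row.get(f):
                    raise ValueError(
                        f"analyte table is corrupt: empty field {f!r} in row {row}"
                    )
            specs.append(
                AnalyteSpec(
                    name=row["name"],
                    atc_code=row["atc_code"],
                    drug_class=row["drug_class"],
                    adq_g=float(row["adq_g"]),
                    excreted_fraction=float(row["excreted_fraction"]),
                    loq_ng_per_l=float(row["loq_ng_per_l"]),
                )
            )
    return specs


def analyte_by_name(
    name: str, table: Sequence[AnalyteSpec] | None = None
) -> AnalyteSpec:
    """Look an analyte up by (case-insensitive) name; KeyError if absent."""
    table = load_analyte_table() if table is None else table
    for spec in table:
        if spec.name.lower() == name.lower():
            return spec
    raise KeyError(f"unknown analyte {name!r}")


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------


def read_sample_series(
    path: str | Path, analyte_table: Sequence[AnalyteSpec] | None = None
) -> list[SampleSeries]:
    """Read a sample CSV (``site,matrix,analyte,timestamp,value``) into series.

    ``value`` is either a concentration in ng/L or the literal token
    ``<LOQ``. A numeric value below the analyte's LOQ is also flagged as
    censored (laboratories occasionally export the raw instrument value).
    Rows are grouped by (site, matrix, analyte) and sorted by time.
    """
    analyte_table = load_analyte_table() if analyte_table is None else analyte_table
    groups: dict[tuple[str, str, str], list[Measurement]] = {}
    specs: dict[str, AnalyteSpec] = {}
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            spec = analyte_by_name(row["analyte"], analyte_table)
            specs[spec.name] = spec
            raw = row["value"].strip()
            try:
                ts = datetime.fromisoformat(row["timestamp"])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: unparseable timestamp {row['timestamp']!r}") from exc
            if raw == CENSORED_TOKEN:
                meas = Measurement(ts, None, censored=True)
            else:
                value = float(raw)
                if value < 0:
                    raise ValueError(f"{path}:{i}: negative concentration {value}")
                if value < spec.loq_ng_per_l:
                    meas = Measurement(ts, None, censored=True)
                else:
                    meas = Measurement(ts, value, censored=False)
            groups.setdefault((row["site"], row["matrix"], spec.name), []).append(meas)
    out = []
    for (site, matrix, analyte_name), meas in groups.items():
        meas.sort(key=lambda m: m.timestamp)
        out.append(SampleSeries(site, matrix, specs[analyte_name], meas))
    return out


def write_sample_series(series: Iterable[SampleSeries], path: str | Path) -> None:
    """Write series back to the sample CSV dialect (censored rows as <LOQ)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site", "matrix", "analyte", "timestamp", "value"])
        for s in series:
            for m in s.measurements:
                value = CENSORED_TOKEN if m.censored else format(m.concentration_ng_per_l, "g")
                writer.writerow([s.site_id, s.matrix, s.analyte.name, m.timestamp.isoformat(), value])


def read_flow_series(path: str | Path) -> list[FlowSeries]:
    """Read a flow CSV: ``site,timestamp,flow_m3_h`` or ``site,date,flow_m3_d``."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        fields = set(reader.fieldnames or [])
        if {"site", "timestamp", "flow_m3_h"} <= fields:
            hourly = True
        elif {"site", "date", "flow_m3_d"} <= fields:
            hourly = False
        else:
            raise ValueError(
                f"{path}: expected columns site,timestamp,flow_m3_h or "
                f"site,date,flow_m3_d; got {sorted(fields)}"
            )
        groups: dict[str, list[tuple[datetime, float]]] = {}
        daily: dict[str, float] = {}
        for row in reader:
            if hourly:
                groups.setdefault(row["site"], []).append(
                    (datetime.fromisoformat(row["timestamp"]), float(row["flow_m3_h"]))
                )
            else:
                daily[row["site"]] = float(row["flow_m3_d"])
    if hourly:
        return [
            FlowSeries(site, records=sorted(recs)) for site, recs in groups.items()
        ]
    return [FlowSeries(site, daily_flow_m3_per_d=q) for site, q in daily.items()]


def validate_catchment(config: CatchmentConfig) -> CatchmentConfig:
    """Validate a catchment and resolve its correction factor F.

    When F is absent it defaults to 1; when a PCT population is given and F
    is absent, F = population_served / pct_population (the fraction of the
    prescription-statistics population whose sewage this WWTP receives).
    """
    if config.population_served <= 0:
        raise ValueError(
            f"{config.wwtp_id}: population_served must be > 0, "
            f"got {config.population_served}"
        )
    if config.wastewater_per_capita_l_per_d <= 0:
        raise ValueError(f"{config.wwtp_id}: wastewater_per_capita_l_per_d must be > 0")
    f = config.correction_factor
    if f is None:
        if config.pct_population is not None:
            if config.pct_population <= 0:
                raise ValueError(f"{config.wwtp_id}: pct_population must be > 0")
            f = config.population_served / config.pct_population
        else:
            f = 1.0
    if not 0 < f <= 1:
        raise ValueError(f"{config.wwtp_id}: correction factor must be in (0, 1], got {f}")
    return replace(config, correction_factor=f)
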