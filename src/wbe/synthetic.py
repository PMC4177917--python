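"""Synthetic WWTP and river datasets with the structure the analysis assumes.

The generator emulates a 24-h composite-sampling campaign at a WWTP plus a
network of river grab-sampling sites:

* a bimodal diurnal flow (morning and evening peaks) whose daily total is
  exactly population x per-capita wastewater volume;
* drug users whose excretion reaches the sewer as discrete toilet-flush
  pulses — a Poisson number of pulses spread over a diurnal toilet-use
  profile, so small catchments show the lumpy hour-to-hour loads that make
  hourly sampling of small populations noisy;
* first-order in-plant removal with a hydraulic retention-time shift;
* dilution of summed upstream per-capita loads into river flow;
* multiplicative lognormal measurement noise and left-censoring at each
  analyte's LOQ.

Every stochastic draw flows from the single seed in ``SimulationConfig``;
the exact pre-noise mass balance is recorded in ``SimTruth`` so recovery
tests have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .core_data import (
    AnalyteSpec,
    FlowSeries,
    Measurement,
    RiverSample,
    RiverSite,
    SampleSeries,
    analyte_by_name,
    load_analyte_table,
)
from .units import L_PER_M3, MG_PER_G, load_to_conc_ng_per_l

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_diurnal_flow",
    "simulate_influent",
    "simulate_effluent",
    "simulate_river_network",
]

_REFERENCE_DAY = datetime(2009, 11, 10)

# Relative propensity of toilet use by hour of day: low overnight, a morning
# peak 07:00-09:00 and a broader evening peak 18:00-22:00.
_TOILET_PROFILE = np.array(
    [0.3, 0.3, 0.3, 0.3, 0.3, 0.6, 1.5, 3.0, 3.0, 2.0, 1.2, 1.0,
     1.0, 1.0, 1.0, 1.0, 1.2, 1.8, 2.5, 2.5, 2.2, 2.0, 1.2, 0.6]
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic sampling campaign."""

    seed: int
    population: int
    wastewater_per_capita_l_per_d: float = 230.0
    n_users_per_analyte: dict[str, int] = field(default_factory=dict)
    dose_g_per_d: dict[str, float] = field(default_factory=dict)
    flushes_per_user_per_d: float = 4.0
    diurnal_amplitude: float = 0.4
    removal_fraction: dict[str, float] = field(default_factory=dict)
    retention_h: float = 8.0
    noise_cv: float = 0.2
    sample_hour: int = 10
    river_sites: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be > 0")
        if not 0 <= self.diurnal_amplitude < 1:
            raise ValueError(
                f"diurnal_amplitude must be in [0, 1), got {self.diurnal_amplitude}"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.flushes_per_user_per_d <= 0:
            raise ValueError("flushes_per_user_per_d must be > 0")
        for name, r in self.removal_fraction.items():
            if not 0 <= r <= 1:
                raise ValueError(f"removal fraction for {name} must be in [0, 1]")


@dataclass
class SimTruth:
    """Exact pre-noise ground truth of one simulated campaign."""

    excreted_mass_mg_per_d: dict[str, float]
    removal_fraction: dict[str, float]
    n_users: dict[str, int]


def _hour_stamps(day: datetime = _REFERENCE_DAY) -> list[datetime]:
    return [day + timedelta(hours=h) for h in range(24)]


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


def simulate_diurnal_flow(config: SimulationConfig) -> FlowSeries:
    """24 hourly flows (m3/h) with morning/evening peaks.

    The daily total is exactly ``population x wastewater_per_capita`` — the
    diurnal modulation is a zero-mean shape scaled by ``diurnal_amplitude``,
    so changing the amplitude redistributes flow within the day without
    altering the total.
    """
    base = config.population * config.wastewater_per_capita_l_per_d / L_PER_M3 / 24
    shape = _TOILET_PROFILE - _TOILET_PROFILE.mean()
    shape = shape / np.abs(shape).max()
    flows = base * (1.0 + config.diurnal_amplitude * shape)
    return FlowSeries(
        site_id="sim",
        records=list(zip(_hour_stamps(), (float(q) for q in flows))),
    )


def _pulse_hourly_masses(
    rng: np.random.Generator,
    total_mass_mg: float,
    n_users: int,
    flushes_per_user: float,
) -> np.ndarray:
    """Distribute a day's excreted mass into hours as discrete flush pulses.

    The pulse count is Poisson with mean n_users x flushes/user; pulses land
    in hours according to the diurnal toilet-use profile. The day's total
    mass is split equally over the realised pulses so the daily mass balance
    is exact while few-user days stay lumpy. A day that draws zero pulses
    for a nonzero mass is bumped to a single pulse: the mass has to reach
    the sewer some hour.
    """
    if total_mass_mg == 0 or n_users == 0:
        return np.zeros(24)
    k = int(rng.poisson(n_users * flushes_per_user))
    if k == 0:
        k = 1
    p = _TOILET_PROFILE / _TOILET_PROFILE.sum()
    counts = rng.multinomial(k, p)
    return counts / k * total_mass_mg


def simulate_influent(
    config: SimulationConfig,
    analyte_table: list[AnalyteSpec] | None = None,
) -> tuple[dict[str, SampleSeries], FlowSeries, SimTruth]:
    """Simulate one day of hourly influent sampling for every configured analyte.

    Returns per-analyte concentration series (censored below LOQ), the
    hourly flow series, and the exact ``SimTruth`` mass balance.
    """
    table = load_analyte_table() if analyte_table is None else analyte_table
    rng = np.random.default_rng(config.seed)
    flow = simulate_diurnal_flow(config)
    flows = np.array(flow.flows_m3_per_h)

    series: dict[str, SampleSeries] = {}
    truth_mass: dict[str, float] = {}
    truth_users: dict[str, int] = {}
    for name in sorted(config.n_users_per_analyte):
        spec = analyte_by_name(name, table)
        n_users = config.n_users_per_analyte[name]
        dose = config.dose_g_per_d.get(name, spec.adq_g)
        total_mg = n_users * dose * spec.excreted_fraction * MG_PER_G
        truth_mass[name] = total_mg
        truth_users[name] = n_users

        masses = _pulse_hourly_masses(
            rng, total_mg, n_users, config.flushes_per_user_per_d
        )
        if np.any((flows == 0) & (masses > 0)):
            raise ValueError(f"{name}: nonzero mass entering a zero-flow hour")
        with np.errstate(invalid="ignore"):
            concs = np.where(
                masses > 0,
                masses * 1.0e6 / (flows * L_PER_M3),
                0.0,
            )
        concs = concs * _lognormal_factors(rng, config.noise_cv, 24)
        series[name] = _censor_series("sim", "influent", spec, concs)

    truth = SimTruth(
        excreted_mass_mg_per_d=truth_mass,
        removal_fraction=dict(config.removal_fraction),
        n_users=truth_users,
    )
    return series, flow, truth


def _censor_series(
    site: str, matrix: str, spec: AnalyteSpec, concs: np.ndarray
) -> SampleSeries:
    measurements = []
    for ts, c in zip(_hour_stamps(), concs):
        if c < spec.loq_ng_per_l:
            measurements.append(Measurement(ts, None, censored=True))
        else:
            measurements.append(Measurement(ts, float(c), censored=False))
    return SampleSeries(site, matrix, spec, measurements)


def simulate_effluent(
    influent: SampleSeries,
    flow: FlowSeries,
    config: SimulationConfig,
) -> SampleSeries:
    """Derive one analyte's effluent series from its influent series.

    The hourly influent load is shifted by the hydraulic retention time
    (circularly within the day, since influent and effluent are sampled
    simultaneously over the same 24 h), attenuated by the configured removal
    fraction, re-noised and re-censored. Censored influent hours carry zero
    load into the plant.
    """
    if config.retention_h < 0:
        raise ValueError(f"retention_h must be nonnegative, got {config.retention_h}")
    spec = influent.analyte
    removal = config.removal_fraction.get(spec.name, 0.0)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash(spec.name), 2])
    )
    flows = np.array(flow.flows_m3_per_h)
    loads_in = np.array(
        [
            0.0 if m.censored else m.concentration_ng_per_l * q * L_PER_M3 / 1.0e6
            for m, q in zip(influent.measurements, flows)
        ]
    )
    shift = int(round(config.retention_h)) % 24
    loads_out = np.roll(loads_in, shift) * (1.0 - removal)
    concs = np.where(flows > 0, loads_out * 1.0e6 / (flows * L_PER_M3), 0.0)
    concs = concs * _lognormal_factors(rng, config.noise_cv, 24)
    return _censor_series(influent.site_id, "effluent", spec, concs)


def _stable_hash(name: str) -> int:
    # deterministic across processes, unlike hash()
    return sum((i + 1) * b for i, b in enumerate(name.encode())) % (2**31)


def simulate_river_network(
    config: SimulationConfig,
    analyte_table: list[AnalyteSpec] | None = None,
    dates: list[datetime] | None = None,
    usage_multiplier: float = 1.0,
) -> list[RiverSite]:
    """Simulate grab samples at river sites ordered downstream.

    Each site's daily load of an analyte is the summed upstream per-capita
    excreted load (after WWTP removal) times its upstream population; the
    grab-sample concentration is that load diluted into the site's daily
    river flow, noised and censored. ``usage_multiplier`` scales drug usage
    uniformly (e.g. a pandemic uplift) without touching the configuration.
    """
    table = load_analyte_table() if analyte_table is None else analyte_table
    if not config.river_sites:
        raise ValueError("config.river_sites is empty")
    pops = [p for p, _ in config.river_sites]
    if any(b < a for a, b in zip(pops, pops[1:])):
        raise ValueError("river sites must be ordered downstream: populations nondecreasing")
    if dates is None:
        dates = [_REFERENCE_DAY]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    per_capita_mg: dict[str, float] = {}
    for name, n_users in config.n_users_per_analyte.items():
        spec = analyte_by_name(name, table)
        dose = config.dose_g_per_d.get(name, spec.adq_g)
        removal = config.removal_fraction.get(name, 0.0)
        per_capita_mg[name] = (
            n_users * dose * spec.excreted_fraction * MG_PER_G
            * (1.0 - removal) * usage_multiplier / config.population
        )

    sites = []
    for i, (pop, flow_m3_d) in enumerate(config.river_sites):
        if flow_m3_d <= 0:
            raise ValueError(f"site {i}: river flow must be > 0")
        samples = []
        for date in dates:
            for name in sorted(per_capita_mg):
                spec = analyte_by_name(name, table)
                load_mg_d = per_capita_mg[name] * pop
                conc = load_to_conc_ng_per_l(load_mg_d, flow_m3_d)
                conc *= float(_lognormal_factors(rng, config.noise_cv, 1)[0])
                stamp = date + timedelta(hours=config.sample_hour)
                if conc < spec.loq_ng_per_l:
                    samples.append(RiverSample(stamp, spec, None, censored=True))
                else:
                    samples.append(RiverSample(stamp, spec, conc, censored=False))
        sites.append(
            RiverSite(
                site_id=f"TC{i + 1}",
                name=f"synthetic site {i + 1}",
                upstream_population=pop,
                flow_m3_per_d=flow_m3_d,
                samples=samples,
            )
        )
    return sites
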