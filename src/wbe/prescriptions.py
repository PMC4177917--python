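"""Forward model from prescription statistics to predicted influent levels.

Predicted influent concentration for a catchment is

    C_w [ng/L] = M x E x F / (P x L)

where M is the daily prescribed mass (g/d) of the drug, E the fraction of
the parent dose excreted in bioactive form, F a correction factor for the
overlap between the prescription-statistics population and the WWTP
catchment, P the catchment population and L the per-capita wastewater
volume (230 L/cap/d by default). The matching predicted excreted mass
(mg/d) is M x E x F x 1000, the quantity compared against measured
environmental loads (MEL).

Annual national statistics are winter-adjusted upward by 9.375% — half the
~18.75% summer/winter swing in UK antibiotic consumption — before being
divided into daily masses. Co-trimoxazole prescriptions are split into
their constituents (0.16 g trimethoprim and 0.8 g sulfamethoxazole per
average daily quantity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .core_data import AnalyteSpec, CatchmentConfig, validate_catchment
from .loads import LoadSummary
from .units import MG_PER_G, NG_PER_G

__all__ = [
    "PrescriptionInput",
    "ForwardPrediction",
    "WINTER_UPLIFT_FRACTION",
    "adq_to_daily_mass",
    "winter_adjust",
    "split_cotrimoxazole",
    "predict_influent_concentration",
    "compare_mel",
]

#: half of the ~18.75% seasonal swing in UK antibiotic prescribing
WINTER_UPLIFT_FRACTION = 0.09375

#: grams of each constituent in one average daily quantity of co-trimoxazole
COTRIMOXAZOLE_TRIMETHOPRIM_G = 0.16
COTRIMOXAZOLE_SULFAMETHOXAZOLE_G = 0.8


@dataclass
class PrescriptionInput:
    """Prescribed amount of one drug over a statistics period.

    Exactly one of ``mass_g`` (grams of active ingredient) or ``adq_count``
    (number of average daily quantities, converted via the analyte's ADQ
    mass) must be provided.
    """

    analyte: AnalyteSpec
    source: Literal["pct_monthly", "nhsbsa_annual"]
    period_days: int
    mass_g: float | None = None
    adq_count: float | None = None

    def __post_init__(self) -> None:
        if (self.mass_g is None) == (self.adq_count is None):
            raise ValueError("provide exactly one of mass_g or adq_count")
        if self.period_days <= 0:
            raise ValueError(f"period_days must be > 0, got {self.period_days}")
        value = self.mass_g if self.mass_g is not None else self.adq_count
        if value < 0:
            raise ValueError("prescribed amount cannot be negative")


@dataclass
class ForwardPrediction:
    """Predicted influent concentration and excreted mass for one analyte."""

    analyte: AnalyteSpec
    predicted_influent_conc_ng_per_l: float
    predicted_excreted_mass_mg_per_d: float
    daily_mass_g: float
    excreted_fraction: float
    correction_factor: float
    population: int
    wastewater_per_capita_l_per_d: float
    winter_uplift_applied: bool = False


def adq_to_daily_mass(presc: PrescriptionInput) -> float:
    """Daily prescribed mass (g/d) over the statistics period."""
    mass = (
        presc.mass_g
        if presc.mass_g is not None
        else presc.adq_count * presc.analyte.adq_g
    )
    return mass / presc.period_days


def winter_adjust(annual_mass_g: float) -> float:
    """Winter-adjusted annual mass: M = M_a + M_s with M_s = M_a x 0.09375."""
    if annual_mass_g < 0:
        raise ValueError(f"annual mass cannot be negative, got {annual_mass_g}")
    return annual_mass_g * (1.0 + WINTER_UPLIFT_FRACTION)


def split_cotrimoxazole(adq_count: float) -> tuple[float, float]:
    """Split co-trimoxazole ADQs into (trimethoprim g, sulfamethoxazole g)."""
    if adq_count < 0:
        raise ValueError(f"ADQ count cannot be negative, got {adq_count}")
    return (
        COTRIMOXAZOLE_TRIMETHOPRIM_G * adq_count,
        COTRIMOXAZOLE_SULFAMETHOXAZOLE_G * adq_count,
    )


def predict_influent_concentration(
    daily_mass_g: float,
    analyte: AnalyteSpec,
    catchment: CatchmentConfig,
    *,
    winter_uplift_applied: bool = False,
) -> ForwardPrediction:
    """Apply the forward model to one analyte's daily prescribed mass."""
    catchment = validate_catchment(catchment)
    volume_l = catchment.daily_wastewater_l()
    if volume_l <= 0:
        raise ValueError("catchment daily wastewater volume must be > 0")
    e = analyte.excreted_fraction
    f = catchment.correction_factor
    conc = daily_mass_g * e * f * NG_PER_G / volume_l
    mass_mg = daily_mass_g * e * f * MG_PER_G
    return ForwardPrediction(
        analyte=analyte,
        predicted_influent_conc_ng_per_l=conc,
        predicted_excreted_mass_mg_per_d=mass_mg,
        daily_mass_g=daily_mass_g,
        excreted_fraction=e,
        correction_factor=f,
        population=catchment.population_served,
        wastewater_per_capita_l_per_d=catchment.wastewater_per_capita_l_per_d,
        winter_uplift_applied=winter_uplift_applied,
    )


def predict_from_prescription(
    presc: PrescriptionInput, catchment: CatchmentConfig
) -> ForwardPrediction:
    """Full forward path: period mass -> (winter adjust) -> daily mass -> C_w.

    Annual national statistics are winter-adjusted; spatially resolved
    monthly statistics are used as-is.
    """
    uplift = presc.source == "nhsbsa_annual"
    raw = (
        presc.mass_g
        if presc.mass_g is not None
        else presc.adq_count * presc.analyte.adq_g
    )
    if uplift:
        raw = winter_adjust(raw)
    daily = raw / presc.period_days
    return predict_influent_concentration(
        daily, presc.analyte, catchment, winter_uplift_applied=uplift
    )


def compare_mel(
    predictions: Sequence[ForwardPrediction],
    measured: Sequence[LoadSummary],
) -> list[dict]:
    """Predicted excreted mass vs measured environmental load, per analyte.

    The ratio predicted/measured flags over- (>1) or under- (<1) prediction;
    analytes whose measured load is zero (all influent hours censored) get
    an undefined ratio rendered "na" downstream.
    """
    measured_by_name = {m.analyte.name: m for m in measured}
    rows = []
    for pred in predictions:
        name = pred.analyte.name
        meas = measured_by_name.get(name)
        row: dict = {
            "analyte": name,
            "predicted_excreted_mg_d": pred.predicted_excreted_mass_mg_per_d,
            "measured_load_mg_d": None if meas is None else meas.daily_load_mg_per_d,
            "ratio": None,
            "direction": "na",
        }
        if meas is not None and meas.daily_load_mg_per_d > 0:
            ratio = pred.predicted_excreted_mass_mg_per_d / meas.daily_load_mg_per_d
            row["ratio"] = ratio
            row["direction"] = (
                "over" if ratio > 1 else "under" if ratio < 1 else "equal"
            )
        rows.append(row)
    return rows
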