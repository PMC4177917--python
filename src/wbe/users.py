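"""Back-estimation of active drug users from measured influent loads.

The inverse of the forward prescription model: given a measured daily mass
load (mg/d) of an excreted drug, the number of people taking it at the
standard daily dose is

    users = (load / 1000) / (dose_g_per_d x excreted_fraction)

Users are reported as real numbers, not rounded counts — a small catchment
legitimately yields a few user-equivalents. Comparing the wastewater-derived
estimate to the number of users predicted from syndromic surveillance gives
a compliance fraction: how much of the dispensed drug was actually consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_data import AnalyteSpec
from .units import MG_PER_G

__all__ = [
    "UserEstimate",
    "NPFS_ANTIVIRAL_RATE",
    "QSURVEILLANCE_ILI_RATE",
    "estimate_users",
    "surveillance_predicted_users",
    "compliance",
]

#: fraction of the national population collecting antiviral courses per week
#: at the autumn 2009 pandemic peak (National Pandemic Flu Service)
NPFS_ANTIVIRAL_RATE = 0.0013

#: influenza-like-illness rate (per person) from QSurveillance for the WWTP
#: sampling week; declined to ~33 per 100,000 three weeks later
QSURVEILLANCE_ILI_RATE = 54.2e-5

#: standard adult oseltamivir regime: 0.075 g twice daily
OSELTAMIVIR_DOSE_G_PER_D = 0.150


@dataclass
class UserEstimate:
    """Wastewater-derived user count, optionally with a compliance fraction."""

    analyte: AnalyteSpec | None
    measured_load_mg_d: float
    dose_g_per_user_per_d: float
    excreted_fraction: float
    estimated_users: float
    surveillance_predicted_users: float | None = None
    compliance_fraction: float | None = None


def estimate_users(
    load_mg_d: float,
    dose_g_d: float,
    excreted_fraction: float,
    analyte: AnalyteSpec | None = None,
) -> UserEstimate:
    """Estimate active users from a measured daily load."""
    if dose_g_d <= 0:
        raise ValueError(f"dose must be > 0, got {dose_g_d}")
    if not 0 < excreted_fraction <= 1:
        raise ValueError(
            f"excreted_fraction must be in (0, 1], got {excreted_fraction}"
        )
    if load_mg_d < 0:
        raise ValueError(f"load cannot be negative, got {load_mg_d}")
    users = (load_mg_d / MG_PER_G) / (dose_g_d * excreted_fraction)
    return UserEstimate(
        analyte=analyte,
        measured_load_mg_d=load_mg_d,
        dose_g_per_user_per_d=dose_g_d,
        excreted_fraction=excreted_fraction,
        estimated_users=users,
    )


def surveillance_predicted_users(population: int, rate: float) -> float:
    """Users predicted by a surveillance rate (cases per person) in a population."""
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if population < 0:
        raise ValueError("population cannot be negative")
    return population * rate


def compliance(estimated_users: float, predicted_users: float) -> float | None:
    """Estimated / surveillance-predicted users, as a fraction.

    Returns None when no users were predicted (compliance undefined).
    """
    if predicted_users < 0 or estimated_users < 0:
        raise ValueError("user counts cannot be negative")
    if predicted_users == 0:
        return None
    return estimated_users / predicted_users


def with_compliance(
    estimate: UserEstimate, population: int, rate: float = NPFS_ANTIVIRAL_RATE
) -> UserEstimate:
    """Fill the surveillance prediction and compliance fields of an estimate."""
    predicted = surveillance_predicted_users(population, rate)
    estimate.surveillance_predicted_users = predicted
    estimate.compliance_fraction = compliance(estimate.estimated_users, predicted)
    return estimate
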