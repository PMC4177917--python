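"""Unit conventions and conversion constants.

Every quantity in this package is carried in one canonical unit:

* concentrations        ng/L
* WWTP / river flows    m3/h (hourly) or m3/d (daily)
* mass loads            mg/d (daily) or mg/h (hourly)
* per-capita loads      ug per capita per day
* prescribed masses     g (grams of active ingredient)

The constants below are the only place where cross-unit arithmetic is
defined; all modules import from here rather than embedding factors.
"""

#: ng per mg
NG_PER_MG = 1.0e6

#: ng per g
NG_PER_G = 1.0e9

#: mg per g
MG_PER_G = 1.0e3

#: ug per mg
UG_PER_MG = 1.0e3

#: litres per cubic metre
L_PER_M3 = 1.0e3

#: hours per day
HOURS_PER_DAY = 24


def conc_flow_to_load_mg(conc_ng_per_l: float, flow_m3: float) -> float:
    """Mass load (mg) carried by ``flow_m3`` of water at ``conc_ng_per_l``.

    ng/L x m3 = ng/L x 1000 L = ug, and /1000 converts ug to mg, so the
    two factors of 1000 cancel into a single division.
    """
    return conc_ng_per_l * flow_m3 * L_PER_M3 / NG_PER_MG


def load_to_conc_ng_per_l(load_mg: float, flow_m3: float) -> float:
    """Concentration (ng/L) of ``load_mg`` dissolved in ``flow_m3`` of water."""
    if flow_m3 <= 0:
        raise ValueError(f"flow must be positive to dilute a load, got {flow_m3}")
    return load_mg * NG_PER_MG / (flow_m3 * L_PER_M3)
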