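from datetime import datetime, timedelta

import pytest

from wbe.core_data import (
    AnalyteSpec,
    FlowSeries,
    Measurement,
    SampleSeries,
    load_analyte_table,
)

DAY = datetime(2009, 11, 10)


@pytest.fixture(scope="session")
def analyte_table():
    return load_analyte_table()


@pytest.fixture(scope="session")
def oc(analyte_table):
    return next(a for a in analyte_table if a.name == "Oseltamivir carboxylate")


@pytest.fixture
def make_series(oc):
    """Build a 24-h hourly SampleSeries from a list of conc/None values."""

    def build(values, analyte=None, matrix="influent", site="wwtp"):
        analyte = analyte or oc
        measurements = []
        for h, v in enumerate(values):
            ts = DAY + timedelta(hours=h)
            if v is None:
                measurements.append(Measurement(ts, None, censored=True))
            else:
                measurements.append(Measurement(ts, float(v), censored=False))
        return SampleSeries(site, matrix, analyte, measurements)

    return build


@pytest.fixture
def make_flow():
    """Build a 24-h hourly FlowSeries from a list of m3/h values."""

    def build(values, site="wwtp"):
        return FlowSeries(
            site,
            records=[(DAY + timedelta(hours=h), float(q)) for h, q in enumerate(values)],
        )

    return build


@pytest.fixture(scope="session")
def simple_analyte():
    """A plain analyte with round-number parameters for arithmetic tests."""
    return AnalyteSpec(
        name="testdrug",
        atc_code="X00XX00",
        drug_class="test",
        adq_g=1.0,
        excreted_fraction=0.5,
        loq_ng_per_l=10.0,
    )
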