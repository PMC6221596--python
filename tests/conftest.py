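import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import edspc

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stream():
    """A small (~30 visits/day, one year + PDSA cycles) synthetic stream."""
    cfg = edspc.GeneratorConfig(daily_visits=30.0, seed=42)
    return edspc.generate_stream(cfg)


@pytest.fixture(scope="session")
def default_stream():
    """One full-scale default stream (~270k visits over 3 years)."""
    return edspc.generate_stream(edspc.GeneratorConfig(seed=20240701))


@pytest.fixture()
def toy_visits():
    return pd.DataFrame(
        {
            "visit_id": ["V1", "V2", "V3"],
            "patient_id": ["P1", "P2", "P3"],
            "arrival": pd.to_datetime(
                ["2014-07-01 08:00:00", "2014-07-02 09:00:00", "2014-07-03 10:00:00"]
            ),
            "departure": pd.to_datetime(
                ["2014-07-01 12:00:00", "2014-07-02 13:00:00", "2014-07-03 14:00:00"]
            ),
            "disposition": ["discharged", "admitted", "discharged"],
        }
    )


@pytest.fixture()
def toy_cultures():
    return pd.DataFrame(
        {
            "culture_id": ["C1", "C2", "C3"],
            "visit_id": ["V1", "V2", "V3"],
            "patient_id": ["P1", "P2", "P3"],
            "ordered_at": pd.to_datetime(
                ["2014-07-01 09:00:00", "2014-07-02 10:00:00", "2014-07-03 11:00:00"]
            ),
            "result": ["no_growth", "growth", "growth"],
            "organism": ["", "Staphylococcus epidermidis", "Streptococcus pneumoniae"],
            "exclusion_flags": ["", "", "oncologic"],
        }
    )
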