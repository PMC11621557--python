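import pandas as pd
import pytest
from hypothesis import settings

import soilrisk as sr

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def refs():
    return sr.load_defaults("references")


@pytest.fixture(scope="session")
def profiles():
    return sr.load_defaults("exposure")


@pytest.fixture(scope="session")
def toxicity():
    return sr.load_defaults("toxicity")


@pytest.fixture(scope="session")
def survey():
    """Deterministic 21-site synthetic survey with the default design."""
    return sr.generate_survey(sr.survey_design(seed=42))


@pytest.fixture()
def tiny_table():
    """Three hand-written sites over the full default panel."""
    df = pd.DataFrame({
        "site_id": ["S1", "S2", "S3"],
        "lat": [13.1, 13.3, 13.6],
        "lon": [74.7, 74.8, 74.9],
        "As": [391.822, 5.0, 0.05],
        "Cd": [17.45, 0.3, 0.01],
        "Cr": [589.209, 75.0, 1.0],
        "Cu": [2499.56, 20.0, 0.5],
        "Fe": [166446.62, 50000.0, 100.0],
        "Ni": [2608.15, 30.0, 0.5],
        "Pb": [2294.235, 20.0, 1.0],
        "Zn": [2625.0, 50.0, 0.5],
    })
    return sr.SampleTable(df, sr.DEFAULT_PANEL)


@pytest.fixture()
def single_as_site():
    """One site carrying only arsenic, at the panel's reference maximum."""
    df = pd.DataFrame({
        "site_id": ["S1"], "lat": [13.33], "lon": [74.74], "As": [391.822],
    })
    return sr.SampleTable(df, ("As",))
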