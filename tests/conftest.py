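from datetime import date

import numpy as np
import pandas as pd
import pytest

from prosopis_water import synthetic_data as sd
from prosopis_water.sapflow_hrm import ProbeGeometry


@pytest.fixture(scope="session")
def probe() -> ProbeGeometry:
    return ProbeGeometry()


@pytest.fixture(scope="session")
def probe_nowound() -> ProbeGeometry:
    return ProbeGeometry(wound_width=None)


@pytest.fixture(scope="session")
def climate() -> sd.ClimateSpec:
    return sd.ClimateSpec(seed=42)


@pytest.fixture(scope="session")
def weather_month(climate) -> pd.DataFrame:
    return sd.generate_weather(climate, date(2017, 1, 1), 30)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
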