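import numpy as np
import pandas as pd
import pytest

from aphidrgr.surface import RGRParams
from aphidrgr.synthetic import (
    FieldSurvey,
    NoiseParams,
    SimulationConfig,
    TemperatureSeries,
    gen_phenology,
    gen_temperature,
    simulate_field_year,
)


@pytest.fixture
def true_params() -> RGRParams:
    return RGRParams(s_m=45.0, a=0.012, b=1.2, k=0.35)


@pytest.fixture
def quiet_season():
    """Noise-free temperature series and phenology for one season."""
    temps = gen_temperature(
        "2001-05-01", 76, noise_params=NoiseParams(sd=0.0, year_sd=0.0), seed=0
    )
    phen = gen_phenology(temps)
    return temps, phen


@pytest.fixture
def default_survey():
    """One default stochastic field-year (survey + weather)."""
    return simulate_field_year(SimulationConfig(seed=11), field_id="F01")


@pytest.fixture
def tiny_survey() -> FieldSurvey:
    """Hand-built 6-week survey with known counts."""
    dates = pd.date_range("2001-05-01", periods=6, freq="7D")
    return FieldSurvey(
        field_id="H1",
        region="test",
        dates=dates,
        tillers=np.full(6, 100),
        aphids=np.array([3, 8, 30, 110, 300, 420]),
        stage=np.array([31.0, 38.0, 47.0, 55.0, 64.0, 71.0]),
    )
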