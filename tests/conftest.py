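import numpy as np
import pytest

from fluexcess.synthetic import (
    DistrictScenario,
    SeriesScenario,
    simulate_district_table,
    simulate_monthly_series,
)


@pytest.fixture(scope="session")
def default_series():
    """Ten-year monthly series with the default January-1890 shock."""
    return simulate_monthly_series(SeriesScenario())


@pytest.fixture(scope="session")
def flat_series():
    """No seasonality, no shock, constant population: pure Poisson."""
    sc = SeriesScenario(seasonal_amplitude=0.0, shock_months=frozenset(),
                        population_growth=0.0)
    return simulate_monthly_series(sc)


@pytest.fixture(scope="session")
def district_panel():
    """Default 182-district lattice panel and its spatial weights."""
    return simulate_district_table(DistrictScenario())


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
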