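import pytest
from hypothesis import settings

from psem import datasets

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lr_decade():
    """The published linear-regression forecast for 2021-2030."""
    return datasets.lr_forecast_2021_2030()


@pytest.fixture(scope="session")
def area_table():
    """The published forecast-decade family counts and populations."""
    return datasets.area_stress_table()
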