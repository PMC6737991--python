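import pytest

from ricessnm import EngineConfig, FarmerInterview, default_products


@pytest.fixture(scope="session")
def cfg():
    return EngineConfig()


@pytest.fixture(scope="session")
def products():
    return default_products()


@pytest.fixture()
def interview():
    """The worked-example field: 4.6 Mg/ha history, 140-day variety."""
    return FarmerInterview(
        field_id="F001",
        growth_duration_days=140,
        seedling_age_days=25,
        historical_yield_GYR=4.6,
        previous_crop_yield=4.5,
    )
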