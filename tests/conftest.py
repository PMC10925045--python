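import pytest

from aeroplume import PlumeParams, ScenarioConfig


@pytest.fixture
def default_params() -> PlumeParams:
    return PlumeParams()


@pytest.fixture
def quiet_config() -> ScenarioConfig:
    """Small noise-free scenario: exact multiplicative structure end to end."""
    return ScenarioConfig(
        n_airports=20,
        years=(2019, 2021),
        noise_sd=0.0,
        station_background_frac=0.0,
        station_noise_sd=0.0,
        seed=7,
    )
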