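import pytest

from strawsim import (
    ModelParameters,
    ScenarioSpec,
    generate_scenario,
    simulate_season,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def default_scenario():
    """Climate, flowering schedule and LAI series of the default synthetic season."""
    return generate_scenario(ScenarioSpec())


@pytest.fixture(scope="session")
def default_result(default_scenario):
    """Daily trajectory of the default synthetic season (seed 0, LAI mode)."""
    env, flowering, leaf_area = default_scenario
    return simulate_season(env, flowering, leaf_area)
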