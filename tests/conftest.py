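import pytest

from ambucea import StrategySpec, default_parameters, generate_fleet


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter set (mortality as stated, 0.040)."""
    return default_parameters()


@pytest.fixture(scope="session")
def params_table4():
    """Defaults under the worked-results-consistent mortality rate (0.035)."""
    return default_parameters(mortality_preset="table4")


@pytest.fixture(scope="session")
def uniform_fleet(params):
    """1,891 ambulances spread uniformly over ages 1..15, all Functioning."""
    return generate_fleet(params.config.fleet_size, scheme="uniform", max_age=15)


@pytest.fixture(scope="session")
def strategy15():
    return StrategySpec(replacement_age=15)


@pytest.fixture(scope="session")
def strategy10():
    return StrategySpec(replacement_age=10)
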