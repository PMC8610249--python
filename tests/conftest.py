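import pytest

from clotfilm import ModelConfig, build_parameters, load_parameters, simulate


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def baseline_rates(params, config):
    return build_parameters(params, config)


@pytest.fixture(scope="session")
def baseline_traj(baseline_rates, config):
    return simulate(baseline_rates, config)
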