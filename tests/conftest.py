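import pytest

from biphasix.synthetic import GeneratorConfig, generate_co_culture_assays


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(noise_sigma_log=0.0, seed=11)


@pytest.fixture
def noiseless_co_table(noiseless_config):
    return generate_co_culture_assays(noiseless_config)


@pytest.fixture
def species_roles():
    return "MYb11", "MYb71"
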