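import pytest
from hypothesis import settings

from microcirc.channels import GroupLabel
from microcirc.synth import SyntheticConfig, generate_session

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> SyntheticConfig:
    return SyntheticConfig(n_samples=2000, seed=20260926)


@pytest.fixture(scope="session")
def control_session(config):
    return generate_session(config, GroupLabel.CONTROL, "control_1", seed=101)


@pytest.fixture(scope="session")
def t2dm_session(config):
    return generate_session(config, GroupLabel.T2DM, "t2dm_1", seed=202)
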