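import pytest
from hypothesis import settings

from ait_cma.defaults import default_config
from ait_cma.engine import compare

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def base_comparison(base_config):
    return compare(base_config)
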