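import pytest
from hypothesis import HealthCheck, settings

import qbdopt as q

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def space():
    return q.clz_sedds_space()


@pytest.fixture(scope="session")
def domain(space):
    return q.MixedDomain.from_space(space)


@pytest.fixture(scope="session")
def study():
    """The bundled 27-run clonazepam S-SEDDS Box-Behnken study."""
    return q.clz_sedds_study()


@pytest.fixture(scope="session")
def pub_models():
    return q.published_models()
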