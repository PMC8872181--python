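import pytest
from hypothesis import HealthCheck, settings

from mitorearr.gene_order import default_registry
from mitorearr.synthetic import SyntheticSpec, generate_record

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def _make(arrangement, seed=1):
    return generate_record(SyntheticSpec(arrangement=arrangement, seed=seed))


@pytest.fixture(scope="session")
def typical_record():
    return _make("typical")


@pytest.fixture(scope="session")
def type_v_record():
    return _make("V")


@pytest.fixture(scope="session")
def type_ix_record():
    return _make("IX")
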