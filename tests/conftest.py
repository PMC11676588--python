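import pytest
from hypothesis import HealthCheck, settings

from forcedeg import Formula, default_element_table
from forcedeg.datasets import load_reference_ms1, load_reference_ms2

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return default_element_table()


@pytest.fixture(scope="session")
def re_parent():
    return Formula(C=48, H=82, O=18)


@pytest.fixture(scope="session")
def reference_ms1():
    return load_reference_ms1()


@pytest.fixture(scope="session")
def reference_ms2():
    return load_reference_ms2()
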