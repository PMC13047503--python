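import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxymet.nirs import NirsProtocol
from oxymet.optics import load_extinction_table
from oxymet.synth import builtin_presets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return load_extinction_table()


@pytest.fixture(scope="session")
def presets():
    return builtin_presets()


@pytest.fixture(scope="session")
def protocol():
    return NirsProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """A fast recording protocol for tests that exercise timing logic."""
    return NirsProtocol(
        sampling_rate=2.0,
        total_duration=60.0,
        anoxia_window=(30.0, 55.0),
        averaging_window=(0.0, 25.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
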