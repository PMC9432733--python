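import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from meaburst import synthetic as syn

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_protocol():
    """Desk-scale protocol: same phase structure, shorter and narrower."""
    return syn.ProtocolSpec(baseline_duration=600.0, exposure_duration=300.0,
                            post_duration=600.0, n_channels=12)


@pytest.fixture(scope="session")
def model():
    return syn.NetworkActivityModel()


@pytest.fixture(scope="session")
def presets():
    return syn.builtin_presets()


@pytest.fixture(scope="session")
def sham_culture(small_protocol, model, presets):
    """One sham-arm culture (spike trains + ground-truth bursts)."""
    return syn.generate_spike_trains(small_protocol, model, presets["sham"], seed=7)


@pytest.fixture(scope="session")
def mu_culture(small_protocol, model, presets):
    return syn.generate_spike_trains(small_protocol, model, presets["mu"], seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
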