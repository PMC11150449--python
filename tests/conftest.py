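import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mgcalab import AcquisitionSettings, SignalScenario, macs3_scenario

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def default_settings():
    return AcquisitionSettings()


@pytest.fixture
def clean_scenario():
    """Noise-free, contamination-free sample calcite at 3.5 mmol/mol."""
    return SignalScenario(true_mgca=3.5)


@pytest.fixture
def contaminated_scenario():
    """Noise-free spot with a 10x Mg surface-contamination interval."""
    return SignalScenario(true_mgca=3.5, contamination_duration=3.0,
                          contamination_factor=10.0)


@pytest.fixture
def standard_scenario():
    return macs3_scenario()


@pytest.fixture
def rng():
    return np.random.default_rng(20240604)
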