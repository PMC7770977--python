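import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polarhythm.design import TimeSeriesDesign

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design() -> TimeSeriesDesign:
    """The field design: 7 timepoints at 4 h intervals over 24 h, 3 replicates."""
    return TimeSeriesDesign()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
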