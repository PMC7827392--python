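import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dormancy

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Packaged default model constants."""
    return dormancy.default_parameters()


@pytest.fixture(scope="session")
def dormancy_trajectory():
    """The quiescent-only one-year dormancy run at default settings."""
    return dormancy.run_series2()


@pytest.fixture(scope="session")
def phase_map():
    """The default 25 x 26 heterogeneous fate map (shared: ~650 runs)."""
    return dormancy.compute_phase_map()


@pytest.fixture(scope="session")
def fig4_runs():
    """Heterogeneous runs at the four reference initial proliferative
    counts within a 5e4-cell inoculum."""
    return {
        count: dormancy.run_series3(count, record_every=10)
        for count in (800.0, 1000.0, 2000.0, 9800.0)
    }
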