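import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eisdry.synthetic import default_frequency_grid

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def grid27() -> np.ndarray:
    """The 27-point log-spaced 0.5-10 kHz sweep used throughout."""
    return default_frequency_grid()


@pytest.fixture
def fast_options():
    """Fit options trimmed for quick unit tests."""
    from eisdry.fitting import FitOptions

    return FitOptions(n_restarts=1, max_iterations=4000, seed=0)
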