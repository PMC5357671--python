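import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gbcsim import ANFParams, SomaParams, SynapseParams, ToneProtocol
from gbcsim.fitting import FitProfile

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=20,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def soma():
    return SomaParams()


@pytest.fixture(scope="session")
def anf():
    return ANFParams()


@pytest.fixture
def silence_protocol():
    return ToneProtocol(cf=500.0, n_repetitions=0)


@pytest.fixture
def short_train():
    """A small tone train for fast end-to-end simulations."""
    return ToneProtocol.sweep_train(500.0, n_repetitions=10)


#: deliberately coarse fit profile for property checks that need whole fits
MINI_PROFILE = FitProfile(n_scan_seeds=2, n_validate_seeds=2,
                          scan_repetitions=20, validate_repetitions=20,
                          n_w=8)
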