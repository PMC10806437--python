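import pytest
from hypothesis import settings

from virodyn import ModelParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def table3():
    """Baseline parameter set used throughout the numerical experiments."""
    return ModelParams(p=1000.0, tau_I=1.25, n_I=10, beta=1e-4, c=7.0, T0=100_000)


@pytest.fixture
def small():
    """Desk-scale parameter set with a narrow burst-size support."""
    return ModelParams(
        p=40.0, tau_I=1.25, n_I=3, beta=1e-3, c=7.0, T0=500, nu_I=0.8
    )
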