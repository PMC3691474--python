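import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hgtclock.amelioration import AmeliorationParams
from hgtclock.synthetic_data import default_curves

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

HOST_GC3 = 0.35


@pytest.fixture(scope="session")
def curves():
    """The true quadratic equilibrium curves used by the generators."""
    return default_curves()


@pytest.fixture(scope="session")
def host_params(curves):
    """Amelioration parameters with the host at equilibrium (GC3 = 0.35)."""
    f1, f2 = curves
    return AmeliorationParams(
        host_equilibrium=(f1.predict(HOST_GC3), f2.predict(HOST_GC3), HOST_GC3)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
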