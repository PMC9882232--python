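import numpy as np
import pytest

from neqmoments import demography as dem
from neqmoments import make_params


@pytest.fixture
def pg_weak():
    """Reference parameter set: s = 1e-2, mu = 1e-6, mu_b = 1e-8, p0 = 1/2N
    for N = 1e4 (gamma' ~ 200, well inside the strong-selection regime)."""
    return make_params(s=1e-2, mu=1e-6, mu_b=1e-8, p0=5e-5)


@pytest.fixture
def pg_round():
    """Round-number set with s' = 0.01 and lambda' = 1e-4 exactly."""
    return make_params(s=0.01 - 1e-6, mu=1e-6, mu_b=0.0, p0=5e-5)


@pytest.fixture
def const_demog():
    return dem.constant(1e4)


@pytest.fixture
def log_grid(pg_weak):
    return np.geomspace(1.0, 50.0 / pg_weak.s_prime, 50)


@pytest.fixture
def resolved_grid(pg_weak):
    """Grid where all four cumulants are well above the floating-point
    cancellation floor (s' t >= 0.5), used for exact-reduction checks."""
    return np.geomspace(0.5 / pg_weak.s_prime, 50.0 / pg_weak.s_prime, 50)
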