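import numpy as np
import pytest

import hybriduq as h


@pytest.fixture(scope="session")
def arsenic_model():
    return h.arsenic_risk_model()


@pytest.fixture(scope="session")
def arsenic_family(arsenic_model):
    """Full-size propagation of the arsenic case study (shared; read-only)."""
    return h.propagate(arsenic_model, n_mc=5000, seed=20170131)


@pytest.fixture(scope="session")
def small_family(arsenic_model):
    """Cheap propagation for structural checks."""
    return h.propagate(arsenic_model, n_mc=200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170131)
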