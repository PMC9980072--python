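import numpy as np
import pytest

from groomens import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def planted_session():
    """A 2 h session with five planted ensembles of mixed response profiles."""
    cfg = SessionConfig(seed=42, ensemble_sizes=[4, 5, 6, 7, 8])
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def null_session():
    """A 2 h session of independent units (no planted ensembles)."""
    cfg = SessionConfig(
        seed=43, n_ensembles=0, ensemble_sizes=[], response_profiles=[]
    )
    return simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
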