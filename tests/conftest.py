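import numpy as np
import pytest

import spikefield as sf


@pytest.fixture(scope="session")
def small_design():
    """Compact headline-scenario session design used by integration tests."""
    return sf.SessionDesign(n_hits=20, n_misses=14, seed=11)


@pytest.fixture(scope="session")
def small_session(small_design):
    return sf.gen_session(small_design)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced shuffle counts for integration tests (seeds fixed)."""
    return sf.RunConfig(n_shuffles_pair_null=20, n_draws_pair_null=2000,
                        n_shuffles_mi=50, n_shuffles_psi=30,
                        n_shuffles_cofire=200, seed=7)


@pytest.fixture(scope="session")
def pipeline_report(small_session, fast_config):
    return sf.run_pipeline(small_session, fast_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
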