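import numpy as np
import pytest

from communityeffect import make_default_params, make_fixture
from communityeffect.core import EPSILON_FAST, EPSILON_SLOW


@pytest.fixture(scope="session")
def slow_params():
    """Canonical rates with the slower communication rate."""
    return make_default_params(epsilon=EPSILON_SLOW, n=300)


@pytest.fixture(scope="session")
def fast_active():
    return make_fixture("fast-active")


@pytest.fixture(scope="session")
def fast_quiescent():
    return make_fixture("fast-quiescent")


@pytest.fixture(scope="session")
def near_threshold():
    return make_fixture("near-threshold")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


FIXTURE_T_END = 6000.0  # seconds; 10000 minutes compressed by the 100x speed-up


@pytest.fixture(scope="session")
def active_ensemble(fast_active):
    """Ten exact SSA replicates of the fast-active fixture, shared across
    tests that only need a well-activated ensemble."""
    from communityeffect import ensemble

    return ensemble(fast_active, FIXTURE_T_END, n_runs=10, seed_base=101,
                    snapshot_times=[FIXTURE_T_END / 40, FIXTURE_T_END])
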