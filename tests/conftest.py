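import numpy as np
import pytest

from ipmeta import build_scenario, simulate_test_statistics

NULL_REPLICATES = 5000
NULL_SEED = 20260131


@pytest.fixture(scope="session")
def null_stats():
    """Per-replicate test statistics under the simulated null.

    Medium-risk additive disease model 3 with r = 0 (marker independent of
    the disease locus), 2000 cases / 2000 controls.  Replicate seeds are
    spawned sequentially from the master seed, so the first k rows coincide
    with a k-replicate run.  Shared across the null-distribution and
    type-I-error tests because the replicates are expensive.
    """
    scenario = build_scenario("medium", "additive", 3, r=0.0, h2=0.010)
    return simulate_test_statistics(scenario, NULL_REPLICATES, seed=NULL_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
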