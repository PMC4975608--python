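import numpy as np
import pytest

from mqreg import GroupedDataset, draw_replicate, make_scenario, run_study


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


def make_grouped(rng, d=20, nj=6, beta=(1.0, 0.5), sg=1.5, se=1.0):
    """Small balanced two-level dataset with known parameters."""
    n = d * nj
    idx = np.repeat(np.arange(d), nj)
    x = rng.uniform(0.0, 10.0, n)
    gamma = rng.normal(0.0, sg, d)
    y = beta[0] + beta[1] * x + gamma[idx] + rng.normal(0.0, se, n)
    X = np.column_stack([np.ones(n), x])
    return GroupedDataset(y=y, X=X, group_idx=idx, group_labels=np.arange(d))


@pytest.fixture
def small_grouped(rng):
    return make_grouped(rng)


@pytest.fixture(scope="session")
def nn_replicate():
    """One replicate of the normal-normal study scenario (fixed seed)."""
    scn = make_scenario("NN", 42)
    return draw_replicate(scn, 43)


@pytest.fixture(scope="session")
def full_study():
    """The complete Monte-Carlo study: 4 scenarios x 3 q x R=500.

    Session-scoped because it is the shared input of all study-level
    assertions; takes a couple of minutes.
    """
    return run_study(
        ("NN", "TT", "NLap", "contaminated"),
        [0.5, 0.75, 0.9],
        500,
        1259,
    )
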