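import numpy as np
import pytest

from nlfc import RoiTimeSeries, SyntheticSpec, generate_cohort

MASTER_SEED = 20170119


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny coupling-free cohort shared by structural tests."""
    spec = SyntheticSpec(
        n_regions=6, n_timepoints=40, group_sizes=(3, 3, 2), seed=MASTER_SEED
    )
    return generate_cohort(spec)


@pytest.fixture
def toy_series(rng):
    return RoiTimeSeries("toy", rng.standard_normal((4, 32)), ["a", "b", "c", "d"])
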