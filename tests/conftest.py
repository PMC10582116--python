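import numpy as np
import pytest

from motormap.core import StatMap
from motormap.synthetic_cohort import CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A minutes-scale cohort: one activating condition on a 10^3 grid."""
    return CohortSpec(
        n_group_a=2,
        n_group_b=2,
        grid_shape=(10, 10, 10),
        conditions=["eyes", "fingers"],
        footprint_centers={"eyes": (3.0, 3.0, 5.0), "fingers": (7.0, 7.0, 5.0)},
        footprint_radius_vox=2.0,
        amplitude=2.0,
        center_jitter_sd_vox=0.0,
        noise_sd=1.0,
        seed=7,
    )


def random_maps(rng, n, shape=(6, 6, 6), loc=0.0, scale=1.0):
    return [StatMap(rng.normal(loc, scale, shape)) for _ in range(n)]
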