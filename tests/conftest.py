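import numpy as np
import pytest

from effconn import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-group cohort, 4 subjects per group, short series."""
    gts = synthetic.default_ground_truths(seed=7)
    return synthetic.simulate_cohort(
        gts, group_sizes={g: 4 for g in gts}, T=150, seed=7
    )


@pytest.fixture(scope="session")
def voxel_setup(small_cohort):
    """Volumes on a small grid plus mixing model for ICA tests."""
    mixing = synthetic.make_mixing_model(
        grid_shape=(12, 12, 8), n_signal=10, n_noise=2,
        voxel_noise_sd=0.5, seed=7,
    )
    volumes = synthetic.simulate_voxel_volumes(small_cohort, mixing, seed=7)
    return small_cohort, mixing, volumes
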