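import numpy as np
import pytest

from dtmt.config import FrameworkConfig
from dtmt.synthetic import PhantomParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-scale config: 32x32 slices, depth-3 U-Net, tiny batches."""
    return FrameworkConfig(input_size=32, depth=3, base_channels=8,
                           iterations=5, batch_size=4, labeled_per_batch=2,
                           data_seed=7, init_seed=7, perturbation_seed=7)


@pytest.fixture(scope="session")
def tiny_phantom_params():
    return PhantomParams(grid_shape=(32, 32, 16), main_blob_radius_range=(5.0, 7.0),
                         n_satellites=1, satellite_radius_range=(1.5, 2.5), seed=0)


@pytest.fixture(scope="session")
def tiny_volumes(tiny_phantom_params):
    return generate_cohort(8, seed=3, params=tiny_phantom_params)
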