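import numpy as np
import pytest

from nmrquant.distributions import ConcentrationSampler
from nmrquant.reference import default_library, make_ppm_grid
from nmrquant.simulator import AugmentationConfig, build_dataset


@pytest.fixture(scope="session")
def small_grid():
    """The full ppm region at a tenth of the working resolution."""
    return make_ppm_grid(-0.32, 10.21, 4600)


@pytest.fixture(scope="session")
def small_library(small_grid):
    return default_library(8, field_strength=400.0, seed=7, grid=small_grid)


@pytest.fixture(scope="session")
def clean_dataset(small_library):
    """Un-augmented, un-normalized mixtures for oracle comparisons."""
    return build_dataset(
        small_library,
        12,
        ConcentrationSampler("uniform"),
        leave_out_scheme="all_present",
        augmentation=AugmentationConfig.disabled(),
        seed=3,
        normalize=False,
    )


@pytest.fixture(scope="session")
def augmented_dataset(small_library):
    """Fully augmented dataset whose records the bound checks inspect."""
    return build_dataset(
        small_library,
        300,
        ConcentrationSampler("uniform"),
        leave_out_scheme="all_present",
        augmentation=AugmentationConfig(),
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
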