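import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from relimap import BrainMask, MeasurementMatrix, VolumeSet
from relimap.simulate import WORKED_EXAMPLE_A, WORKED_EXAMPLE_B

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def worked_matrix() -> MeasurementMatrix:
    """Five subjects, two occasions, occasion B = 3 x occasion A."""
    return MeasurementMatrix.from_occasions([WORKED_EXAMPLE_A, WORKED_EXAMPLE_B])


def random_matrix(rng, n=6, k=3, signal_sd=3.0, noise_sd=1.0) -> MeasurementMatrix:
    subj = rng.normal(0, signal_sd, size=(n, 1))
    return MeasurementMatrix(subj + rng.normal(0, noise_sd, size=(n, k)))


@pytest.fixture
def small_volume_set() -> VolumeSet:
    """Random 4x4x4 grid, 8 subjects, 2 occasions."""
    rng = np.random.default_rng(1234)
    data = rng.normal(0, 1, size=(8, 2, 4, 4, 4)) + rng.normal(
        0, 1.5, size=(8, 1, 1, 1, 1)
    )
    return VolumeSet(data, np.diag([3.0, 3.0, 3.0, 1.0]))


@pytest.fixture
def full_mask(small_volume_set) -> BrainMask:
    return BrainMask(
        np.ones(small_volume_set.grid_dims, dtype=bool), small_volume_set.affine
    )
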