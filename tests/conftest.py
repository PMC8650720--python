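import numpy as np
import pytest

from nigrastab.grids import BinaryMask
from nigrastab.phantom import PhantomParams, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def small_params():
    """Compact phantom settings used across tests (fast to generate)."""
    return PhantomParams(
        grid_shape=(24, 24, 16),
        spacing=(1.0, 1.0, 1.0),
        nucleus_radius_range=(2.4, 2.9),
        bilateral_offset_frac=0.15,
    )


@pytest.fixture(scope="session")
def one_subject(small_params):
    return generate_subject(small_params, "PD", seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(small_params):
    return generate_cohort(4, 4, small_params, seed=0)


@pytest.fixture()
def box_mask():
    """A 4x3x2 solid box inside a 12x12x10 grid."""
    m = np.zeros((12, 12, 10), dtype=np.uint8)
    m[4:8, 5:8, 4:6] = 1
    return BinaryMask(m, (1.0, 1.0, 1.0))
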