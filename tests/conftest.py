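import logging

import numpy as np
import pytest

import flairtex as fx

# empty-ROI / dropped-voxel warnings are part of normal operation on tiny
# fixtures; keep test output readable
logging.getLogger("flairtex").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and bias-free separable phantom with one uniform lesion."""
    spec = fx.PhantomSpec(grid_shape=(48, 48, 8), noise_sd=0.0,
                          bias_amplitude=0.0, rng_seed=1)
    lesions = fx.LesionSpec(centers=[(38, 24, 4)], radii_mm=[3.0],
                            intensity_offset=40.0, heterogeneity=0.0)
    img, masks = fx.generate_phantom(spec, lesions)
    return spec, lesions, img, masks


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom with a textured lesion."""
    spec = fx.PhantomSpec(grid_shape=(48, 48, 8), rng_seed=3)
    lesions = fx.LesionSpec(centers=[(38, 24, 4)], radii_mm=[3.5],
                            intensity_offset=40.0, heterogeneity=10.0)
    img, masks = fx.generate_phantom(spec, lesions)
    return spec, lesions, img, masks


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort on a desk-scale grid, processed to a table."""
    spec = fx.PhantomSpec(grid_shape=(40, 40, 8), rng_seed=5)
    cohort = fx.CohortSpec(n_subjects=12, rng_seed=5,
                           heterogeneity_range=(5.0, 15.0))
    result = fx.generate_cohort(spec, cohort)
    table = fx.build_cohort_table(result)
    return result, table


def assert_mask_equal(a: np.ndarray, b: np.ndarray, msg: str = ""):
    assert (a == b).all(), msg or "masks differ"
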