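import numpy as np
import pytest

import voxwalk as vw


@pytest.fixture(scope="session")
def small_phantom():
    """Small two-sphere phantom with dense truth and sparse annotation."""
    img, dense = vw.two_object_phantom(contrast=60, noise_sd=8, rng_seed=11,
                                       shape=(48, 32, 32))
    sparse = vw.sparsify_labels(dense, every_k=8)
    return img, dense, sparse


@pytest.fixture
def uniform_volume():
    """Uniform 9x9x9 intensity volume (all walks unbiased)."""
    return vw.IntensityVolume(np.full((9, 9, 9), 100, dtype=np.uint8),
                              dtype_class="uint8")


@pytest.fixture
def single_seed_set():
    """Factory: SeedSet with one seed; sigma defaults to the clamp."""

    def make(img, position, label=1, sigma=1.0):
        from voxwalk.engine import SeedSet

        pos = np.array([position], dtype=np.int64)
        return SeedSet(
            positions=pos,
            labels=np.array([label], dtype=np.int64),
            axis_codes=np.zeros(1, dtype=np.int8),
            sigmas=np.array([sigma], dtype=np.float64),
            intensities=np.array([float(img.data[position])], dtype=np.float64),
            interior=np.zeros(1, dtype=bool),
            annotated_planes={"z": [int(position[0])]},
        )

    return make
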