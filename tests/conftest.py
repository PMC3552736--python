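import numpy as np
import pytest

import specpaint as sp


@pytest.fixture(scope="session")
def truth():
    """Default-configuration phantom (full anatomical resolution)."""
    return sp.make_phantom(seed=1)


@pytest.fixture(scope="session")
def composites(truth):
    return sp.render_composites(truth, sp.default_table())


@pytest.fixture(scope="session")
def recovered(truth, composites):
    return sp.recover_ratio_map(
        composites, sp.default_table(), truth.slice_maxima, truth.config.csi
    )


@pytest.fixture(scope="session")
def coarse_config():
    """Reduced-resolution grids for registration tests (cost control)."""
    return sp.PhantomConfig(
        anat_spacing_mm=(1.8, 1.8, 3.0), ct_spacing_mm=(1.96, 1.96, 2.5)
    )


@pytest.fixture(scope="session")
def coarse_truth(coarse_config):
    return sp.make_phantom(coarse_config, seed=3)


@pytest.fixture
def small_mask():
    """Single voxel in an isotropic 1 mm grid, for expansion oracles."""
    arr = np.zeros((9, 9, 9), dtype=bool)
    arr[4, 4, 4] = True
    return sp.BinaryMask(array=arr, spacing=(1.0, 1.0, 1.0), modality="MASK")
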