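import numpy as np
import pytest

from qmrpipe import acquisition as acq
from qmrpipe.phantom import build_label_map, roi_masks


@pytest.fixture(scope="session")
def small_geometry():
    """Compact phantom geometry keeping per-test fits fast."""
    return dict(matrix=(32, 32), n_slices=7)


@pytest.fixture(scope="session")
def tumor_phantom(small_geometry):
    return build_label_map(lesion_layout="tumor", **small_geometry)


@pytest.fixture(scope="session")
def rn_phantom(small_geometry):
    return build_label_map(lesion_layout="rn", **small_geometry)


@pytest.fixture(scope="session")
def tumor_rois(tumor_phantom):
    return roi_masks(tumor_phantom, erosion=2)


@pytest.fixture(scope="session")
def rn_rois(rn_phantom):
    return roi_masks(rn_phantom, erosion=2)


@pytest.fixture(scope="session")
def vfa_acq():
    return acq.default_vfa()


@pytest.fixture(scope="session")
def mems_acq():
    return acq.default_mems()


@pytest.fixture(scope="session")
def dwi_acq():
    return acq.default_dwi()


@pytest.fixture(scope="session")
def mt_acq():
    return acq.default_mt()


@pytest.fixture(scope="session")
def dmrs_acq():
    return acq.default_dmrs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
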