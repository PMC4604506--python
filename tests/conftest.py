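import numpy as np
import pytest

from perifocal.phantom import PhantomSpec, ResectionSpec, make_phantom_labels, make_post_volume
from perifocal.volumes import VoxelGrid


@pytest.fixture(scope="session")
def phantom_labels():
    """Default 96-voxel bilateral phantom, shared read-only across tests."""
    return make_phantom_labels(PhantomSpec())


@pytest.fixture(scope="session")
def left_resection(phantom_labels):
    """Default left anterior temporal resection with its truth cavity."""
    post, truth = make_post_volume(
        phantom_labels, ResectionSpec(side="left", posterior_extent_mm=40.0)
    )
    return post, truth


@pytest.fixture()
def small_grid():
    return VoxelGrid.isotropic((32, 32, 32), 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
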