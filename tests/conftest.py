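import numpy as np
import pytest

from petpattern.synthetic import PhantomSpec, default_geometry
from petpattern.volume_io import BrainMask, VolumeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry() -> VolumeGeometry:
    return default_geometry(n=8, voxel_mm=2.0)


@pytest.fixture
def small_mask(small_geometry) -> BrainMask:
    vox = np.zeros(small_geometry.shape, dtype=bool)
    vox[1:7, 1:7, 1:7] = True
    return BrainMask(geometry=small_geometry, voxels=vox)


@pytest.fixture
def tiny_spec() -> PhantomSpec:
    """A low-resolution phantom spec for fast end-to-end unit tests."""
    return PhantomSpec(geometry=default_geometry(n=16, voxel_mm=4.0),
                       mask_radii_mm=(26.0, 28.0, 24.0), seed=3)


def make_blobs(n_per_class: int, p: int, sep: float, seed: int):
    """Two Gaussian classes separated along a random direction."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = rng.normal(size=(2 * n_per_class, p))
    t = np.array([1] * n_per_class + [-1] * n_per_class)
    X += np.outer(t * sep / 2.0, direction)
    return X, t


@pytest.fixture
def blobs():
    return make_blobs
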