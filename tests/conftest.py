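import numpy as np
import pytest

from nichedist import BinaryMask, make_phantom


def make_mask(shape=(16, 16, 16), affine=None, fg=()):
    """Small helper: binary mask with the given foreground indices."""
    data = np.zeros(shape, dtype=np.uint8)
    for idx in fg:
        data[tuple(idx)] = 1
    if affine is None:
        affine = np.eye(4)
    return BinaryMask(data=data, affine=affine)


def ball_mask(shape, affine, center_mm, radius_mm):
    """Digitized sphere: voxels whose centers lie within radius of center."""
    idx = np.indices(shape).reshape(3, -1).T
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    inside = np.linalg.norm(world - np.asarray(center_mm), axis=1) <= radius_mm
    data = np.zeros(shape, dtype=np.uint8)
    data[tuple(idx[inside].T)] = 1
    return BinaryMask(data=data, affine=np.asarray(affine, float))


@pytest.fixture(scope="session")
def phantom():
    """The default 2 mm template-space phantom (built once per session)."""
    return make_phantom()


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
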