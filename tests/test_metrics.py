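import numpy as np
import pytest
from scipy import ndimage

from nichedist import (
    BinaryMask,
    NicheGeometry,
    border_distance,
    center_distance,
    contact_flags,
    lesion_centroid,
    lesion_volume_ml,
    measure_lesion,
)
from nichedist.metrics import EmptyMaskError

from conftest import ball_mask, make_mask


def point_niche(points):
    return NicheGeometry(name="SGZ", kind="point_set", elements=np.atleast_2d(points))


def band_niche(indices, affine=np.eye(4), shape=(32, 32, 32)):
    idx = np.atleast_2d(indices)
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return NicheGeometry(
        name="SVZ",
        kind="voxel_band",
        elements=world,
        affine=np.asarray(affine, float),
        grid_shape=shape,
        voxel_indices=np.asarray(idx, int),
    )


def test_centroid_examples():
    np.testing.assert_allclose(
        lesion_centroid(make_mask((8, 8, 8), fg=[(5, 5, 5)])), (5, 5, 5)
    )
    np.testing.assert_allclose(
        lesion_centroid(make_mask((8, 8, 8), fg=[(0, 0, 0), (4, 0, 0)])), (2, 0, 0)
    )
    sphere = ball_mask((41, 41, 41), np.eye(4) + np.diag([0, 0, 0, 0]), (10, 20, 10), 6.0)
    assert np.linalg.norm(lesion_centroid(sphere) - (10, 20, 10)) <= 0.5


def test_volume_examples():
    m = make_mask((10, 10, 10), fg=[(i, j, k) for i in range(10) for j in range(10) for k in range(10)])
    assert lesion_volume_ml(m) == pytest.approx(1.0)
    aff2 = np.diag([2.0, 2.0, 2.0, 1.0])
    assert lesion_volume_ml(make_mask((4, 4, 4), affine=aff2, fg=[(1, 1, 1)])) == pytest.approx(0.008)
    aniso = np.diag([0.5, 0.5, 5.0, 1.0])
    m = make_mask((10, 10, 10), affine=aniso, fg=[(i, j, k) for i in range(10) for j in range(10) for k in range(8)])
    assert lesion_volume_ml(m) == pytest.approx(1.0)  # 800 x 1.25 mm3
    assert lesion_volume_ml(make_mask((4, 4, 4))) == 0.0


def test_border_distance_examples():
    # 3-4-5 triangle to a point niche
    m = make_mask((8, 8, 8), fg=[(0, 0, 0)])
    assert border_distance(m, point_niche([3.0, 4.0, 0.0])) == pytest.approx(5.0)
    # sharing a voxel with the band -> exactly zero
    m = make_mask((8, 8, 8), fg=[(2, 2, 2), (3, 2, 2)])
    band = band_niche([(3, 2, 2), (6, 6, 6)], shape=(8, 8, 8))
    assert border_distance(m, band) == 0.0
    assert center_distance(m, point_niche([2.5, 2.0, 12.0])) == pytest.approx(10.0)


def test_distance_brute_force_oracle(rng):
    """Implementation equals the exhaustive pairwise minimum."""
    for _ in range(25):
        fg = rng.integers(0, 20, size=(50, 3))
        affine = np.diag([*rng.uniform(0.8, 2.5, size=3), 1.0])
        affine[:3, 3] = rng.uniform(-20, 20, size=3)
        mask = make_mask((20, 20, 20), affine=affine, fg=fg)
        band_idx = rng.integers(0, 20, size=(40, 3))
        niche = band_niche(band_idx, affine=affine, shape=(20, 20, 20))
        lw = mask.foreground_world()
        bw = niche.elements
        brute = np.min(np.linalg.norm(lw[:, None, :] - bw[None, :, :], axis=2))
        contact = bool(set(map(tuple, mask.foreground_indices())) & set(map(tuple, band_idx)))
        expected = 0.0 if contact else brute
        assert border_distance(mask, niche) == pytest.approx(expected, abs=1e-9)
        cb = np.min(np.linalg.norm(lw.mean(axis=0) - bw, axis=1))
        assert center_distance(mask, niche) == pytest.approx(cb, abs=1e-9)


def test_border_not_greater_than_center(rng):
    for _ in range(20):
        fg = rng.integers(0, 15, size=(30, 3))
        mask = make_mask((15, 15, 15), fg=fg)
        niche = point_niche(rng.uniform(-10, 25, size=(2, 3)))
        assert border_distance(mask, niche) <= center_distance(mask, niche) + 1e-9


def test_translation_isometry(rng):
    fg = rng.integers(0, 12, size=(25, 3))
    mask = make_mask((12, 12, 12), fg=fg)
    pts = rng.uniform(0, 12, size=(3, 3))
    v = np.array([13.0, -7.0, 2.0])
    shifted_affine = np.eye(4)
    shifted_affine[:3, 3] = v
    mask_t = make_mask((12, 12, 12), affine=shifted_affine, fg=fg)
    for p, pt in ((point_niche(pts), point_niche(pts + v)),):
        assert border_distance(mask, p) == pytest.approx(border_distance(mask_t, pt), abs=1e-6)
        assert center_distance(mask, p) == pytest.approx(center_distance(mask_t, pt), abs=1e-6)


def test_dilation_monotonicity(rng):
    data = np.zeros((20, 20, 20), dtype=np.uint8)
    data[8:11, 8:11, 8:11] = 1
    niche = point_niche([(1.0, 2.0, 3.0), (18.0, 17.0, 4.0)])
    prev = np.inf
    for _ in range(4):
        mask = BinaryMask(data=data.copy(), affine=np.eye(4))
        d = border_distance(mask, niche)
        assert d <= prev + 1e-12
        prev = d
        data = ndimage.binary_dilation(data).astype(np.uint8)


def test_spherical_lesion_analytic():
    affine = np.eye(4)
    seed = np.array([20.0, 20.0, 20.0])
    target = np.array([20.0, 20.0, 38.0])
    d = np.linalg.norm(target - seed)
    r = 6.0
    mask = ball_mask((41, 41, 41), affine, seed, r)
    niche = point_niche(target)
    assert border_distance(mask, niche) == pytest.approx(max(0.0, d - r), abs=0.5)
    assert center_distance(mask, niche) == pytest.approx(d, abs=0.5)


def test_contact_flags_and_consistency(rng):
    # lesion voxel containing the SGZ point
    m = make_mask((8, 8, 8), fg=[(4, 4, 4)])
    svz = band_niche([(0, 0, 0)], shape=(8, 8, 8))
    sgz = point_niche([4.2, 3.9, 4.4])
    assert contact_flags(m, svz, sgz) == (False, True)
    # far lesion: both false
    far = point_niche([100.0, 0.0, 0.0])
    assert contact_flags(m, band_niche([(0, 0, 7)], shape=(8, 8, 8)), far) == (False, False)
    # cohort-level: contact count equals count of zero border distances
    zeros = flags = 0
    for _ in range(100):
        fg = rng.integers(0, 10, size=(8, 3))
        mask = make_mask((10, 10, 10), fg=fg)
        band = band_niche(rng.integers(0, 10, size=(5, 3)), shape=(10, 10, 10))
        b = border_distance(mask, band)
        zeros += b == 0.0
        flags += contact_flags(mask, band, far)[0]
    assert zeros == flags


def test_measure_lesion_invariants():
    mask = ball_mask((41, 41, 41), np.eye(4), (20, 20, 20), 5.0)
    svz = band_niche([(2, 2, 2), (3, 2, 2)], shape=(41, 41, 41))
    sgz = point_niche([(35.0, 35.0, 35.0)])
    res = measure_lesion(mask, svz, sgz, subject_id="s1", group="astrocytoma_IDHmut")
    assert res.border_svz_mm <= res.center_svz_mm
    assert res.border_sgz_mm <= res.center_sgz_mm
    assert res.contact_svz == (res.border_svz_mm == 0.0)
    assert res.volume_ml == pytest.approx(lesion_volume_ml(mask))


def test_empty_mask_errors():
    empty = make_mask((5, 5, 5))
    niche = point_niche([1.0, 1.0, 1.0])
    for fn in (lesion_centroid,):
        with pytest.raises(EmptyMaskError):
            fn(empty)
    with pytest.raises(EmptyMaskError):
        border_distance(empty, niche)
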