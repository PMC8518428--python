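import numpy as np
import pytest

from livernav.volume import (Mask, Volume, gaussian_smooth, minmax_normalize,
                             read_volume, resample, resample_to_grid, threshold,
                             write_volume)


def _hu_volume(seed=0, shape=(6, 7, 8)):
    rng = np.random.default_rng(seed)
    vox = rng.integers(-1000, 1000, size=shape).astype(np.int16)
    return Volume(vox, (2.5, 1.0, 1.5), origin_mm=(-10.0, 3.0, 0.0))


def test_volume_validation():
    with pytest.raises(ValueError):
        Volume(np.zeros((4, 4)), (1, 1, 1))
    with pytest.raises(ValueError):
        Volume(np.zeros((4, 4, 4)), (0, 1, 1))
    with pytest.raises(ValueError):
        Volume(np.full((2, 2, 2), 2.0), (1, 1, 1), intensity_kind="normalized")
    with pytest.raises(ValueError):
        Mask(np.full((2, 2, 2), 3), (1, 1, 1))


def test_index_mm_roundtrip():
    v = _hu_volume()
    idx = (3, 2, 5)
    np.testing.assert_allclose(v.mm_to_index(v.index_to_mm(idx)), idx)
    np.testing.assert_allclose(v.index_to_mm((0, 0, 0)), v.origin_mm)


@pytest.mark.parametrize("name", ["vol.mhd", "vol.nii.gz", "dicomdir"])
def test_io_roundtrip(tmp_path, name):
    v = _hu_volume()
    path = tmp_path / name
    write_volume(v, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.voxels, v.voxels)
    np.testing.assert_allclose(back.spacing_mm, v.spacing_mm)
    np.testing.assert_allclose(back.origin_mm, v.origin_mm, atol=1e-5)


def test_mask_io_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    m = Mask((rng.random((5, 6, 7)) > 0.5).astype(np.uint8), (2.0, 1.0, 1.0))
    write_volume(m, tmp_path / "m.mhd")
    back = read_volume(tmp_path / "m.mhd", as_mask=True)
    np.testing.assert_array_equal(back.voxels, m.voxels)


def test_dicom_slices_ordered_by_position(tmp_path):
    v = _hu_volume(seed=2, shape=(5, 4, 4))
    d = tmp_path / "series"
    write_volume(v, d)
    # shuffle file names; the reader must still order by slice position
    files = sorted(d.iterdir())
    renamed = [f.with_name(f"x_{i}.dcm") for i, f in enumerate(reversed(files))]
    for f, r in zip(reversed(files), renamed):
        f.rename(r)
    back = read_volume(d)
    np.testing.assert_array_equal(back.voxels, v.voxels)


def test_read_missing_path():
    with pytest.raises(IOError):
        read_volume("/nonexistent/volume.mhd")


def test_minmax_normalize():
    v = _hu_volume()
    n = minmax_normalize(v)
    assert n.intensity_kind == "normalized"
    assert n.voxels.min() == 0.0 and n.voxels.max() == 1.0
    lo, hi = v.voxels.min(), v.voxels.max()
    np.testing.assert_allclose(n.voxels, (v.voxels - lo) / (hi - lo))
    with pytest.raises(ValueError, match="constant"):
        minmax_normalize(Volume(np.zeros((3, 3, 3)), (1, 1, 1)))


def test_resample_preserves_extent_and_constants():
    v = Volume(np.full((10, 10, 10), 7.0), (2.0, 2.0, 2.0))
    out = resample(v, 1.0)
    assert out.shape == (20, 20, 20)
    np.testing.assert_allclose(out.voxels, 7.0)
    assert out.spacing_mm == (1.0, 1.0, 1.0)


def test_resample_mask_is_binary():
    rng = np.random.default_rng(3)
    m = Mask((rng.random((10, 10, 10)) > 0.5).astype(np.uint8), (2.0, 2.0, 2.0))
    out = resample(m, 3.0)
    assert set(np.unique(out.voxels)) <= {0, 1}
    assert isinstance(out, Mask)


def test_resample_to_grid_identity():
    v = _hu_volume()
    vals = np.asarray(v.voxels, float)
    out = resample_to_grid(vals, v, v)
    np.testing.assert_allclose(out, vals)


def test_gaussian_smooth_constant_exact_and_mm_sigma():
    v = Volume(np.full((8, 8, 8), 100.0), (2.0, 2.0, 2.0))
    np.testing.assert_allclose(gaussian_smooth(v, 5.0).voxels, 100.0)
    # anisotropic: smoothing only along z leaves an x-edge intact
    step = np.zeros((8, 8, 8))
    step[:, :, 4:] = 1.0
    sv = Volume(step, (1.0, 1.0, 1.0))
    out = gaussian_smooth(sv, (3.0, 0.0, 0.0))
    np.testing.assert_allclose(out.voxels, step, atol=1e-12)


def test_threshold_directions():
    v = Volume(np.array([[[-500.0, -300.0, 0.0]]]), (1, 1, 1))
    np.testing.assert_array_equal(threshold(v, -300.0).voxels, [[[0, 1, 1]]])
    np.testing.assert_array_equal(threshold(v, -300.0, "below").voxels, [[[1, 0, 0]]])
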