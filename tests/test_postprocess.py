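import numpy as np
import pytest

from livernav.phantom import PhantomSpec, generate_phantom, generate_probability_fixture
from livernav.postprocess import (MaskPostprocessor, PostprocessConfig, binarize,
                                  erode, keep_largest_component, postprocess)
from livernav.volume import Mask, Volume


def flood_components(mask, connectivity):
    """Brute-force connected components by breadth-first flood fill."""
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
                if (a, b, c) != (0, 0, 0)]
    labels = np.zeros(mask.shape, int)
    cur = 0
    for seed in np.argwhere(mask):
        seed = tuple(seed)
        if labels[seed]:
            continue
        cur += 1
        stack = [seed]
        labels[seed] = cur
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= ni < si for ni, si in zip(n, mask.shape)) \
                        and mask[n] and not labels[n]:
                    labels[n] = cur
                    stack.append(n)
    return labels, cur


def brute_erode(mask):
    """One 6-neighbourhood erosion; outside the grid counts as background."""
    out = np.zeros_like(mask)
    for z, y, x in np.argwhere(mask):
        keep = True
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            n = (z + dz, y + dy, x + dx)
            if not all(0 <= ni < si for ni, si in zip(n, mask.shape)) or not mask[n]:
                keep = False
                break
        out[z, y, x] = keep
    return out.astype(np.uint8)


def test_largest_component_matches_flood_fill():
    rng = np.random.default_rng(0)
    for conn in (6, 26):
        cfg = PostprocessConfig(connectivity=conn)
        for _ in range(15):
            m = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8)
            got = keep_largest_component(Mask(m, (1, 1, 1)), cfg)
            labels, n = flood_components(m, conn)
            if n == 0:
                assert not got.voxels.any()
                continue
            sizes = [(labels == i).sum() for i in range(1, n + 1)]
            assert got.voxels.sum() == max(sizes)
            # the kept voxels form exactly one brute-force component
            kept = set(np.unique(labels[got.bool]))
            assert len(kept) == 1


def test_erode_matches_brute_force():
    rng = np.random.default_rng(1)
    cfg = PostprocessConfig(erosions=1)
    for _ in range(15):
        m = (rng.random((8, 8, 8)) > 0.4).astype(np.uint8)
        got = erode(Mask(m, (1, 1, 1)), cfg)
        np.testing.assert_array_equal(got.voxels, brute_erode(m))


def test_four_erosions_shrink_cube_by_four_per_side():
    m = np.zeros((14, 14, 14), np.uint8)
    m[2:12, 2:12, 2:12] = 1
    out = erode(Mask(m, (1, 1, 1)))  # default 4 erosions
    expected = np.zeros_like(m)
    expected[6:8, 6:8, 6:8] = 1
    np.testing.assert_array_equal(out.voxels, expected)


def test_binarize_threshold_half():
    v = Volume(np.array([[[0.0, 0.49, 0.5, 0.51, 1.0]]]), (1, 1, 1),
               intensity_kind="normalized")
    np.testing.assert_array_equal(binarize(v).voxels, [[[0, 0, 1, 1, 1]]])


def test_binarize_rejects_out_of_range():
    v = Volume(np.full((2, 2, 2), 1.5), (1, 1, 1))
    with pytest.raises(ValueError, match="probability"):
        binarize(v)


def test_postprocess_removes_spurious_blob():
    _, truth = generate_phantom(PhantomSpec(shape=(40, 48, 48), spacing_mm=3.0, seed=7))
    proba = generate_probability_fixture(truth, blob_offset_mm=(30, -40, -50),
                                         blob_radius_mm=9.0, seed=7)
    from scipy import ndimage

    raw = binarize(proba)
    _, n_raw = ndimage.label(raw.voxels)
    assert n_raw >= 2  # the blob is a separate raw component
    out = postprocess(proba)
    _, n_out = ndimage.label(out.voxels, ndimage.generate_binary_structure(3, 3))
    assert n_out == 1


def test_postprocess_empty_probability_stays_empty():
    v = Volume(np.zeros((8, 8, 8)), (1, 1, 1), intensity_kind="normalized")
    assert not postprocess(v).voxels.any()


def test_transformer_roundtrip_params():
    pp = MaskPostprocessor(erosions=2)
    assert pp.get_params()["erosions"] == 2
    pp.set_params(threshold=0.3)
    assert pp.get_params()["threshold"] == 0.3
    with pytest.raises(ValueError, match="invalid parameter"):
        pp.set_params(bogus=1)


def test_transformer_matches_function():
    _, truth = generate_phantom(PhantomSpec(shape=(32, 40, 40), spacing_mm=4.0, seed=3))
    proba = generate_probability_fixture(truth, seed=3)
    a = MaskPostprocessor().fit().transform(proba)
    b = postprocess(proba)
    np.testing.assert_array_equal(a.voxels, b.voxels)


def test_config_validation():
    with pytest.raises(ValueError):
        PostprocessConfig(threshold=1.5)
    with pytest.raises(ValueError):
        PostprocessConfig(connectivity=8)
    with pytest.raises(ValueError):
        PostprocessConfig(erosions=-1)
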