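import numpy as np
import pytest

from livernav.tiling import (TileSet, TileSpec, assemble, make_inference_tiles,
                             make_training_tiles, stack_channels)
from livernav.volume import Mask, Volume


def brute_count(shape, edge, offsets):
    """Enumerate training-tile placements by brute force."""
    total = 0
    for off in (0, *offsets):
        counts = []
        for size in shape:
            starts = [s for s in range(-off, size, edge) if s + edge > 0 and s < size]
            counts.append(len(starts))
        total += int(np.prod(counts))
    return total


def _prob_tiles(tiles):
    return TileSet(tiles=tiles.tiles[:, 0], placements=tiles.placements,
                   source_shape=tiles.source_shape, mode=tiles.mode)


def test_inference_roundtrip_identity():
    rng = np.random.default_rng(0)
    spec = TileSpec()
    for _ in range(10):
        shape = tuple(rng.integers(32, 71, size=3))
        x = rng.random((1, *shape)).astype(np.float32)
        tiles = make_inference_tiles(x, spec)
        out = assemble(_prob_tiles(tiles))
        np.testing.assert_array_equal(out, x[0])


def test_training_tile_count_spec_example():
    x = np.zeros((1, 64, 64, 64), np.float32)
    spec = TileSpec(train_offsets=(8, 16, 24))
    tiles = make_training_tiles(x, None, spec)
    assert len(tiles) == 89
    assert len(tiles) == brute_count((64, 64, 64), 32, (8, 16, 24))


def test_training_tile_count_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(5):
        shape = tuple(rng.integers(32, 60, size=3))
        offsets = (8, 16, 24)
        x = np.zeros((1, *shape), np.float32)
        tiles = make_training_tiles(x, None, TileSpec(train_offsets=offsets))
        assert len(tiles) == brute_count(shape, 32, offsets)


def test_label_appended_and_padded_with_background():
    rng = np.random.default_rng(2)
    x = rng.random((2, 40, 40, 40)).astype(np.float32)
    y = Mask((rng.random((40, 40, 40)) > 0.5).astype(np.uint8), (1, 1, 1))
    spec = TileSpec(train_offsets=(16,))
    tiles = make_training_tiles(x, y, spec)
    assert tiles.tiles.shape[1] == 3  # 2 feature channels + label
    # tiles shifted to a negative start carry label padding 0 there
    neg = [i for i, p in enumerate(tiles.placements) if (p < 0).all()]
    assert neg
    t = tiles.tiles[neg[0]]
    p = tiles.placements[neg[0]]
    assert not t[2, : -p[0]].any()
    # in-range voxels reproduce the label
    np.testing.assert_array_equal(
        t[2, -p[0]:, -p[1]:, -p[2]:],
        y.voxels[: 32 + p[0], : 32 + p[1], : 32 + p[2]])


def test_training_tiles_content_matches_source():
    rng = np.random.default_rng(3)
    x = rng.random((1, 40, 40, 40)).astype(np.float32)
    spec = TileSpec(train_offsets=(8,))
    tiles = make_training_tiles(x, None, spec)
    for t, (sz, sy, sx) in zip(tiles.tiles, tiles.placements):
        for _ in range(5):
            i, j, k = rng.integers(0, 32, size=3)
            src = (sz + i, sy + j, sx + k)
            if all(0 <= c < 40 for c in src):
                assert t[0, i, j, k] == x[0][src]
            else:
                assert t[0, i, j, k] == 0.0


def test_slices2d_mode_one_tile_per_slice():
    x = np.random.default_rng(4).random((3, 5, 8, 8)).astype(np.float32)
    spec = TileSpec(mode="slices2d")
    tiles = make_inference_tiles(x, spec)
    assert len(tiles) == 5
    assert tiles.tiles.shape == (5, 3, 8, 8)
    out = assemble(_prob_tiles(tiles))
    np.testing.assert_array_equal(out, x[0])


def test_volume_smaller_than_cube_rejected():
    x = np.zeros((1, 16, 40, 40), np.float32)
    with pytest.raises(ValueError, match="smaller than one cube"):
        make_inference_tiles(x, TileSpec())


def test_stack_channels_requires_normalized():
    v = Volume(np.zeros((4, 4, 4)) + 50.0, (1, 1, 1), intensity_kind="HU")
    with pytest.raises(ValueError, match="normalized"):
        stack_channels(v)


def test_stack_channels_with_features_order_and_range(small_phantom):
    from livernav.bodynav import extract_features
    from livernav.volume import minmax_normalize

    vol, _ = small_phantom
    f = extract_features(vol)
    x = stack_channels(minmax_normalize(vol), f)
    assert x.shape == (5, *vol.shape)
    assert x.min() >= 0.0 and x.max() <= 1.0
    # channel 1 is the (normalized) sagittal SDF: monotone along x on a row
    mid = tuple(s // 2 for s in vol.shape)
    row = x[1][mid[0], mid[1], :]
    assert row[-1] > row[0]


def test_spec_validation():
    with pytest.raises(ValueError):
        TileSpec(mode="bogus")
    with pytest.raises(ValueError):
        TileSpec(train_offsets=(40,))
    with pytest.raises(ValueError):
        TileSpec(cube_shape=(0, 32, 32))
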