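"""Cutting volumes into network-ready tiles and lossless reassembly.

Two modes: per-axial-slice 2D tiles, or 3D cubes (default 32^3). Training
cubes are additionally cut from copies of the grid shifted by the configured
offsets (default 8, 16, 24 voxels in each direction), which multiplies the
amount of training data roughly fourfold. Inference uses the unshifted,
disjoint stride-equal-to-edge grid, so reassembly is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bodynav import BodyNavFeatures
from .volume import Mask, Volume, minmax_normalize

__all__ = ["TileSpec", "TileSet", "stack_channels", "make_training_tiles",
           "make_inference_tiles", "assemble"]

#: fixed channel order of multi-channel grids
CHANNEL_ORDER = ("intensity", "sdf_sagittal", "sdf_coronal", "sdf_axial", "sdf_surface")


@dataclass
class TileSpec:
    """Tiling configuration."""

    mode: str = "cubes3d"  # or "slices2d"
    cube_shape: tuple[int, int, int] = (32, 32, 32)
    train_offsets: tuple[int, ...] = (8, 16, 24)
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("cubes3d", "slices2d"):
            raise ValueError(f"mode must be 'cubes3d' or 'slices2d', got {self.mode!r}")
        self.cube_shape = tuple(int(c) for c in self.cube_shape)
        if any(c <= 0 for c in self.cube_shape):
            raise ValueError("cube_shape must be positive")
        self.train_offsets = tuple(int(o) for o in self.train_offsets)
        if any(o <= 0 or o >= min(self.cube_shape) for o in self.train_offsets):
            raise ValueError("offsets must be positive and smaller than the cube edge")


@dataclass
class TileSet:
    """Ordered tiles plus the placement needed to reassemble them.

    ``tiles[i]`` has shape ``(channels, *tile_shape)``; ``placements[i]`` is
    the (z, y, x) start index of the tile in the source grid (may be negative
    for shifted training grids; out-of-range voxels are padding).
    """

    tiles: np.ndarray  # (n, channels, ...) stacked
    placements: np.ndarray  # (n, 3) start indices
    source_shape: tuple[int, int, int]
    mode: str

    def __len__(self) -> int:
        return len(self.tiles)


def stack_channels(v: Volume, f: BodyNavFeatures | None = None) -> np.ndarray:
    """Stack the normalized intensity with the (min-max normalized) SDF
    channels into a ``(C, z, y, x)`` grid, channel order
    intensity, sagittal, coronal, axial, surface.

    Each SDF channel is rescaled to [0, 1] per volume with the same min-max
    normalization applied to intensities.
    """
    if v.intensity_kind != "normalized":
        raise ValueError("stack_channels expects a normalized intensity volume")
    channels = [np.asarray(v.voxels, dtype=np.float32)]
    if f is not None:
        for name, sdf in zip(CHANNEL_ORDER[1:], f.channels):
            if sdf.shape != v.shape:
                raise ValueError(f"{name} grid {sdf.shape} does not match volume {v.shape}")
            lo, hi = float(sdf.min()), float(sdf.max())
            if hi == lo:
                raise ValueError(f"{name} is constant; cannot normalize")
            channels.append(((sdf - lo) / (hi - lo)).astype(np.float32))
    return np.stack(channels)


def _grid_starts(size: int, edge: int, offset: int) -> list[int]:
    """Start indices of a stride-``edge`` tiling of the grid shifted by
    ``offset`` (tiles may extend past either end; padding fills the rest)."""
    n = -(-(size + offset) // edge)  # ceil
    return [k * edge - offset for k in range(n)]


def _extract(x: np.ndarray, start, shape, pad_value: float) -> np.ndarray:
    """Tile of ``x`` (channel-first) starting at ``start``, padded where the
    window leaves the grid."""
    c = x.shape[0]
    out = np.full((c, *shape), pad_value, dtype=x.dtype)
    src, dst = [], []
    for s, e, n in zip(start, shape, x.shape[1:]):
        lo, hi = max(s, 0), min(s + e, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
    out[(slice(None), *dst)] = x[(slice(None), *src)]
    return out


def make_training_tiles(x: np.ndarray, y: Mask | None, spec: TileSpec) -> TileSet:
    """Training tiles: all offset grids (offset 0 plus each training offset)
    in ``cubes3d`` mode, or one tile per axial slice in ``slices2d`` mode.

    The label (if given) is appended as the last channel, padded with
    background.
    """
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError("expected a (channels, z, y, x) grid")
    shape = x.shape[1:]
    if y is not None:
        if y.shape != shape:
            raise ValueError(f"label shape {y.shape} does not match grid {shape}")
        lab = y.voxels.astype(x.dtype)[None]
    else:
        lab = None

    if spec.mode == "slices2d":
        tiles = []
        placements = []
        for k in range(shape[0]):
            t = x[:, k]
            if lab is not None:
                t = np.concatenate([t, lab[:, k]])
            tiles.append(t)
            placements.append((k, 0, 0))
        return TileSet(np.stack(tiles), np.asarray(placements), shape, spec.mode)

    if any(n < c for n, c in zip(shape, spec.cube_shape)):
        raise ValueError(
            f"volume {shape} is smaller than one cube {spec.cube_shape}; pad the volume first"
        )
    full = x if lab is None else np.concatenate([x, lab])
    tiles, placements = [], []
    for off in (0, *spec.train_offsets):
        starts = [_grid_starts(n, c, off) for n, c in zip(shape, spec.cube_shape)]
        for sz in starts[0]:
            for sy in starts[1]:
                for sx in starts[2]:
                    # labels padded with background (0), matching the
                    # normalized-intensity padding
                    tiles.append(_extract(full, (sz, sy, sx), spec.cube_shape, spec.pad_value))
                    placements.append((sz, sy, sx))
    return TileSet(np.stack(tiles), np.asarray(placements), shape, spec.mode)


def make_inference_tiles(x: np.ndarray, spec: TileSpec) -> TileSet:
    """Disjoint, covering tiling for inference (offset 0 only); placements
    are unique and every source voxel is covered exactly once."""
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError("expected a (channels, z, y, x) grid")
    shape = x.shape[1:]
    if spec.mode == "slices2d":
        return make_training_tiles(x, None, spec)
    if any(n < c for n, c in zip(shape, spec.cube_shape)):
        raise ValueError(
            f"volume {shape} is smaller than one cube {spec.cube_shape}; pad the volume first"
        )
    tiles, placements = [], []
    starts = [_grid_starts(n, c, 0) for n, c in zip(shape, spec.cube_shape)]
    for sz in starts[0]:
        for sy in starts[1]:
            for sx in starts[2]:
                tiles.append(_extract(x, (sz, sy, sx), spec.cube_shape, spec.pad_value))
                placements.append((sz, sy, sx))
    return TileSet(np.stack(tiles), np.asarray(placements), shape, spec.mode)


def assemble(pred: TileSet) -> np.ndarray:
    """Reassemble single-channel prediction tiles into the source grid.

    Inference placements are disjoint, so each voxel takes the value of the
    tile that owns it; padding outside the source grid is discarded.
    """
    shape = tuple(pred.source_shape)
    out = np.full(shape, np.nan, dtype=np.float64)
    for tile, start in zip(pred.tiles, pred.placements):
        t = tile[0] if tile.ndim == len(shape) + 1 else tile
        if pred.mode == "slices2d":
            out[start[0]] = t
            continue
        src, dst = [], []
        for s, e, n in zip(start, t.shape, shape):
            lo, hi = max(s, 0), min(s + e, n)
            if lo >= hi:
                break
            dst.append(slice(lo, hi))
            src.append(slice(lo - s, hi - s))
        else:
            out[tuple(dst)] = t[tuple(src)]
    if np.isnan(out).any():
        missing = np.argwhere(np.isnan(out))
        raise ValueError(
            f"assembly left {len(missing)} voxels uncovered (first at {missing[0]})"
        )
    return out
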