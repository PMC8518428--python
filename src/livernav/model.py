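"""U-Net liver segmentation on tiled CT volumes.

:class:`UNetSegmenter` wraps the network engine behind a fit/predict
interface operating directly on :class:`~livernav.volume.Volume` objects:
training stacks the normalized intensity with the optional body-navigation
SDF channels, cuts the volumes into tiles (2D slices or 3D cubes), and
optimizes a class-weighted binary cross-entropy with Adam; prediction tiles
the volume, runs the network and reassembles per-voxel liver probabilities.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .bodynav import BodyNavFeatures
from .tiling import (TileSet, TileSpec, assemble, make_inference_tiles,
                     make_training_tiles, stack_channels)
from .volume import Mask, Volume, minmax_normalize

logger = logging.getLogger(__name__)

__all__ = ["UNetSegmenter"]


def _as_pair(item) -> tuple[Volume, BodyNavFeatures | None]:
    if isinstance(item, Volume):
        return item, None
    v, f = item
    return v, f


class UNetSegmenter(BaseEstimator):
    """2D/3D U-Net segmenter with optional position-feature channels.

    Parameters
    ----------
    mode : {"cubes3d", "slices2d"}
        3D 32^3 cubes (default) or per-axial-slice 2D tiles.
    use_position_features : bool
        When true, ``fit``/``predict`` expect ``(volume, features)`` pairs
        and the four SDF channels are appended to the intensity channel.
    levels, base_filters, dropout_rate, dropout_levels
        Network architecture (see :class:`livernav.nn.UNet`).
    epochs, batch_size, learning_rate, seed
        Training setup. ``batch_size=None`` selects the mode default
        (4 for cubes, 32 for slices).
    cube_shape, train_offsets
        Tiling of the training volumes; offsets shift extra tile grids to
        augment the training set.

    Attributes (set by ``fit``)
    ---------------------------
    net_ : trained :class:`livernav.nn.UNet`
    history_ : :class:`livernav.nn.TrainHistory`
    class_weights_ : (background, foreground) loss weights
    n_channels_ : number of input channels
    """

    def __init__(self, mode: str = "cubes3d", use_position_features: bool = True,
                 levels: int = 5, base_filters: int = 64, dropout_rate: float = 0.5,
                 dropout_levels: tuple[int, ...] = (4, 5), epochs: int = 5,
                 batch_size: int | None = None, learning_rate: float = 0.01,
                 seed: int = 0, cube_shape: tuple[int, int, int] = (32, 32, 32),
                 train_offsets: tuple[int, ...] = (8, 16, 24)):
        self.mode = mode
        self.use_position_features = use_position_features
        self.levels = levels
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self.dropout_levels = dropout_levels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.cube_shape = cube_shape
        self.train_offsets = train_offsets

    # ------------------------------------------------------------------
    def _tile_spec(self) -> TileSpec:
        return TileSpec(mode=self.mode, cube_shape=tuple(self.cube_shape),
                        train_offsets=tuple(self.train_offsets))

    def _effective_batch(self) -> int:
        if self.batch_size is not None:
            return int(self.batch_size)
        return 4 if self.mode == "cubes3d" else 32

    def _stack(self, item) -> np.ndarray:
        v, f = _as_pair(item)
        if self.use_position_features and f is None:
            raise ValueError(
                "use_position_features=True requires (volume, features) pairs")
        if v.intensity_kind != "normalized":
            v = minmax_normalize(v)
        return stack_channels(v, f if self.use_position_features else None)

    def fit(self, X, y):
        """Train on volumes ``X`` (Volume or (Volume, BodyNavFeatures) each)
        with liver masks ``y``."""
        X = list(X)
        y = list(y)
        if len(X) != len(y) or not X:
            raise ValueError("X and y must be equally long and non-empty")
        spec = self._tile_spec()
        tiles = []
        for item, mask in zip(X, y):
            grid = self._stack(item)
            if not isinstance(mask, Mask):
                raise ValueError("labels must be Mask objects")
            tiles.append(make_training_tiles(grid, mask, spec).tiles)
        tiles = np.concatenate(tiles)
        feats, labels = tiles[:, :-1], tiles[:, -1]
        self.n_channels_ = feats.shape[1]
        self.class_weights_ = nn.class_weights(labels)
        logger.info("training on %d tiles, %d channels, class weights %s",
                    len(feats), self.n_channels_, np.round(self.class_weights_, 3))
        self.net_ = nn.UNet(
            in_channels=self.n_channels_, ndim=3 if self.mode == "cubes3d" else 2,
            levels=self.levels, base_filters=self.base_filters,
            dropout_rate=self.dropout_rate, dropout_levels=tuple(self.dropout_levels),
            seed=self.seed)
        cfg = nn.TrainConfig(epochs=self.epochs, batch_size=self._effective_batch(),
                             learning_rate=self.learning_rate, seed=self.seed)
        self.history_ = nn.train_network(self.net_, feats, labels, cfg,
                                         weights=self.class_weights_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("this UNetSegmenter is not fitted yet; call fit first")

    def predict_proba(self, X):
        """Per-voxel liver probability Volume(s) for one item or a list."""
        self._check_fitted()
        single = isinstance(X, (Volume, tuple))
        items = [X] if single else list(X)
        spec = self._tile_spec()
        out = []
        for item in items:
            v, _ = _as_pair(item)
            grid = self._stack(item)
            tiles = make_inference_tiles(grid, spec)
            probs = nn.predict_tiles(self.net_, tiles.tiles, self._effective_batch())
            vol = assemble(TileSet(tiles=probs, placements=tiles.placements,
                                   source_shape=tiles.source_shape, mode=tiles.mode))
            out.append(Volume(vol, v.spacing_mm, v.origin_mm, intensity_kind="normalized"))
        return out[0] if single else out

    def predict(self, X):
        """Binary liver Mask(s) at probability threshold 0.5 (apply the
        postprocessing module separately for the full cleanup)."""
        proba = self.predict_proba(X)
        single = isinstance(proba, Volume)
        vols = [proba] if single else proba
        masks = [Mask((p.voxels >= 0.5).astype(np.uint8), p.spacing_mm, p.origin_mm)
                 for p in vols]
        return masks[0] if single else masks

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Persist a fitted segmenter (config + weights) to an .npz file."""
        self._check_fitted()
        meta = {"params": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in self.get_params().items()},
                "n_channels": int(self.n_channels_),
                "class_weights": list(self.class_weights_),
                "epoch_losses": list(self.history_.epoch_losses)}
        arrays = {f"param_{i:03d}": p for i, (p, _) in enumerate(self.net_.parameters())}
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        """Restore a segmenter written by :meth:`save`."""
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in meta["params"].items()}
            est = cls(**params)
            est.n_channels_ = meta["n_channels"]
            est.class_weights_ = tuple(meta["class_weights"])
            est.net_ = nn.UNet(
                in_channels=est.n_channels_, ndim=3 if est.mode == "cubes3d" else 2,
                levels=est.levels, base_filters=est.base_filters,
                dropout_rate=est.dropout_rate, dropout_levels=tuple(est.dropout_levels),
                seed=est.seed)
            stored = [data[f"param_{i:03d}"] for i in range(len(est.net_.parameters()))]
            for (p, _), s in zip(est.net_.parameters(), stored):
                if p.shape != s.shape:
                    raise ValueError(f"stored weights do not fit the architecture: "
                                     f"{s.shape} vs {p.shape}")
                p[...] = s
            est.history_ = nn.TrainHistory(epoch_losses=meta["epoch_losses"],
                                           class_weights=est.class_weights_)
        return est
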