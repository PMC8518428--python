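"""Volumetric CT images: containers, file I/O, and voxel-level primitives.

Axis convention, used everywhere in the package
-----------------------------------------------
Arrays are indexed ``(z, y, x)`` with

* ``z`` -- craniocaudal axis, slice index increasing toward the head,
* ``y`` -- anteroposterior axis, index increasing posteriorly,
* ``x`` -- left-right axis, index increasing toward the patient's left.

All millimetre coordinates are voxel-centre coordinates,
``origin_mm + index * spacing_mm``, in the same ``(z, y, x)`` order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "Mask",
    "VolumeFormat",
    "read_volume",
    "write_volume",
    "minmax_normalize",
    "resample",
    "resample_to_grid",
    "gaussian_smooth",
    "threshold",
]


class VolumeFormat(str, Enum):
    """Supported on-disk representations."""

    dicom_dir = "dicom_dir"
    metaimage = "metaimage"
    nifti = "nifti"


@dataclass
class Volume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar grid in Hounsfield units or normalized intensities.
    spacing_mm : tuple of float
        Per-axis voxel spacing ``(z, y, x)``; strictly positive.
    origin_mm : tuple of float
        Millimetre coordinate of voxel ``(0, 0, 0)``.
    intensity_kind : {"HU", "normalized"}
        ``"normalized"`` volumes must lie in [0, 1].
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "HU"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxel grid must be 3D and non-empty, got shape {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive reals, got {self.spacing_mm}")
        if self.intensity_kind not in ("HU", "normalized"):
            raise ValueError(f"unknown intensity_kind {self.intensity_kind!r}")
        if self.intensity_kind == "normalized":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"normalized volume out of [0, 1]: range [{lo}, {hi}]")
        logger.debug(
            "Volume shape=%s spacing=%s range=[%.1f, %.1f] kind=%s",
            self.voxels.shape, self.spacing_mm,
            float(self.voxels.min()), float(self.voxels.max()), self.intensity_kind,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_mm(self, idx) -> np.ndarray:
        """Millimetre coordinate of a (possibly fractional) voxel index ``(z, y, x)``."""
        return np.asarray(self.origin_mm) + np.asarray(idx, dtype=float) * np.asarray(self.spacing_mm)

    def mm_to_index(self, mm) -> np.ndarray:
        return (np.asarray(mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def with_voxels(self, voxels: np.ndarray, intensity_kind: str | None = None) -> "Volume":
        """New volume on the same grid with different voxel values."""
        return replace(
            self, voxels=voxels,
            intensity_kind=self.intensity_kind if intensity_kind is None else intensity_kind,
        )


@dataclass
class Mask:
    """A binary labelling of a :class:`Volume` grid (values restricted to {0, 1})."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq}")
        self.voxels = arr.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


# ---------------------------------------------------------------------------
# File I/O (SimpleITK handles the three formats; it returns (z, y, x) arrays
# and (x, y, z) geometry vectors, so geometry tuples are reversed here).
# ---------------------------------------------------------------------------

def _import_sitk():
    import SimpleITK as sitk

    return sitk


def _infer_format(path: Path) -> VolumeFormat:
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        return VolumeFormat.metaimage
    if name.endswith((".nii", ".nii.gz")):
        return VolumeFormat.nifti
    if path.is_dir() or "." not in name:
        # an existing directory, or an extensionless target to be created
        return VolumeFormat.dicom_dir
    raise ValueError(f"cannot infer volume format from {path}")


def read_volume(path, format: VolumeFormat | str | None = None, *, as_mask: bool = False):
    """Read a volume (or mask) from DICOM series directory, MetaImage, or NIfTI.

    Slices of a DICOM series are ordered by their position along the axial
    axis regardless of file naming. Spacing must be present in the metadata;
    it is never silently assumed.
    """
    sitk = _import_sitk()
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    fmt = VolumeFormat(format) if format is not None else _infer_format(path)

    if fmt is VolumeFormat.dicom_dir:
        if not path.is_dir():
            raise IOError(f"dicom_dir format requires a directory, got {path}")
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesIDs(str(path))
        if not series:
            raise IOError(f"no readable DICOM series in {path}")
        # sorted by image position along the slice normal
        files = reader.GetGDCMSeriesFileNames(str(path), series[0])
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:  # pragma: no cover - message path
            raise IOError(f"could not read volume {path}: {exc}") from exc

    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got array shape {arr.shape}")
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    if any(s <= 0 for s in spacing):
        raise IOError(f"{path}: missing or invalid voxel spacing {spacing}")
    logger.debug("read %s: shape=%s spacing=%s", path, arr.shape, spacing)
    if as_mask:
        return Mask((arr != 0).astype(np.uint8), spacing, origin)
    return Volume(arr, spacing, origin, intensity_kind="HU")


def write_volume(v: Volume | Mask, path, format: VolumeFormat | str | None = None) -> None:
    """Write a volume or mask so that :func:`read_volume` recovers it.

    Masks and integer volumes are stored as unsigned 8-bit / signed 16-bit
    labels; floating-point (e.g. normalized) volumes keep a float voxel type.
    DICOM output is written as a series of axial slice files.
    """
    sitk = _import_sitk()
    path = Path(path)
    fmt = VolumeFormat(format) if format is not None else _infer_format(path)

    arr = v.voxels
    if isinstance(v, Mask):
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.floating):
        if np.allclose(arr, np.round(arr)) and v.intensity_kind == "HU":
            arr = np.round(arr).astype(np.int16)
        else:
            arr = arr.astype(np.float32)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(v.spacing_mm)))
    img.SetOrigin(tuple(reversed(v.origin_mm)))

    try:
        if fmt is VolumeFormat.dicom_dir:
            _write_dicom_series(sitk, img, arr, path)
        else:
            path.parent.mkdir(parents=True, exist_ok=True)
            sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write volume to {path}: {exc}") from exc
    logger.debug("wrote %s: shape=%s spacing=%s", path, arr.shape, v.spacing_mm)


def _write_dicom_series(sitk, img, arr, path: Path) -> None:
    """Write one DICOM file per axial slice with geometry tags set."""
    if not np.issubdtype(arr.dtype, np.integer):
        # DICOM CT stores integer pixel data; HU volumes round-trip exactly.
        img = sitk.Cast(img, sitk.sitkInt16)
    path.mkdir(parents=True, exist_ok=True)
    writer = sitk.ImageFileWriter()
    writer.KeepOriginalImageUIDOn()
    sz, sy, sx = (img.GetSpacing()[2], img.GetSpacing()[1], img.GetSpacing()[0])
    import time

    uid_root = "1.2.826.0.1.3680043.8.498."
    stamp = time.strftime("%Y%m%d%H%M%S")
    series_uid = uid_root + "1." + stamp
    study_uid = uid_root + "2." + stamp
    nz = img.GetSize()[2]
    for k in range(nz):
        sl = img[:, :, k]
        pos = img.TransformIndexToPhysicalPoint((0, 0, k))
        for tag, val in [
            ("0008|0016", "1.2.840.10008.5.1.4.1.1.2"),  # CT storage
            ("0008|0018", f"{series_uid}.{k}"),
            ("0008|0060", "CT"),
            ("0020|000d", study_uid),
            ("0020|000e", series_uid),
            ("0020|0013", str(k + 1)),
            ("0020|0032", "\\".join(f"{p:.6f}" for p in pos)),
            ("0020|0037", "1\\0\\0\\0\\1\\0"),
            ("0018|0050", f"{sz:.6f}"),
            ("0018|0088", f"{sz:.6f}"),
            ("0028|0030", f"{sx:.6f}\\{sy:.6f}"),
        ]:
            sl.SetMetaData(tag, val)
        writer.SetFileName(str(path / f"slice_{k:04d}.dcm"))
        writer.Execute(sl)


# ---------------------------------------------------------------------------
# Intensity and geometry primitives
# ---------------------------------------------------------------------------

def minmax_normalize(v: Volume) -> Volume:
    """Rescale intensities to [0, 1]: ``(x - x_min) / (x_max - x_min)``.

    Raises on a constant volume (the rescaling is undefined there, and a
    constant CT volume always indicates an upstream bug).
    """
    x = np.asarray(v.voxels, dtype=np.float64)
    x_min, x_max = float(x.min()), float(x.max())
    if x_max == x_min:
        raise ValueError("cannot min-max normalize a constant volume (x_max == x_min)")
    out = (x - x_min) / (x_max - x_min)
    return Volume(out, v.spacing_mm, v.origin_mm, intensity_kind="normalized")


def resample(v: Volume | Mask, target_spacing_mm) -> Volume | Mask:
    """Resample to a new spacing, preserving physical extent within one voxel.

    New shape is ``round(old_shape * old_spacing / new_spacing)``. Intensities
    are interpolated linearly, masks by nearest neighbour. The origin (centre
    of voxel (0,0,0)) is kept fixed.
    """
    target = np.asarray([float(s) for s in np.atleast_1d(target_spacing_mm)], dtype=float)
    if target.size == 1:
        target = np.repeat(target, 3)
    if target.size != 3 or np.any(target <= 0):
        raise ValueError(f"target spacing must be 3 positive values, got {target_spacing_mm}")
    old_spacing = np.asarray(v.spacing_mm)
    old_shape = np.asarray(v.shape)
    new_shape = np.maximum(np.round(old_shape * old_spacing / target).astype(int), 0)
    if np.any(new_shape < 1):
        raise ValueError(f"target spacing {target} collapses an axis (new shape {new_shape})")

    # index of each new voxel centre expressed on the old grid
    coords = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(new_shape, target, old_spacing)],
        indexing="ij",
    )
    is_mask = isinstance(v, Mask)
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(
        np.asarray(v.voxels, dtype=np.uint8 if is_mask else np.float64),
        np.stack([c.ravel() for c in coords]),
        order=order, mode="nearest",
    ).reshape(tuple(new_shape))
    if is_mask:
        return Mask(out, tuple(target), v.origin_mm)
    return Volume(out, tuple(target), v.origin_mm, intensity_kind=v.intensity_kind)


def resample_to_grid(values: np.ndarray, src: Volume | Mask, like: Volume | Mask) -> np.ndarray:
    """Linearly sample a scalar grid defined on ``src``'s grid at the voxel
    centres of ``like``'s grid (used to bring working-resolution fields back
    to the native grid)."""
    coords = np.meshgrid(
        *[
            (np.arange(n) * sl + ol - os) / ss
            for n, sl, ol, os, ss in zip(
                like.shape, like.spacing_mm, like.origin_mm, src.origin_mm, src.spacing_mm
            )
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        np.asarray(values, dtype=np.float64),
        np.stack([c.ravel() for c in coords]),
        order=1, mode="nearest",
    ).reshape(like.shape)


def gaussian_smooth(v: Volume, sigma_mm) -> Volume:
    """Separable Gaussian filter with per-axis sigma given in millimetres.

    Sigmas are converted to voxels through the spacing, so anisotropic
    physical kernels (e.g. 100 x 15 x 15 mm spine smoothing) are supported.
    Edge handling replicates the border value, which keeps constants exact
    and avoids darkening the body at image borders.
    """
    sigma = np.asarray([float(s) for s in np.atleast_1d(sigma_mm)], dtype=float)
    if sigma.size == 1:
        sigma = np.repeat(sigma, 3)
    if np.any(sigma < 0):
        raise ValueError(f"sigma_mm must be >= 0, got {sigma_mm}")
    sigma_vox = sigma / np.asarray(v.spacing_mm)
    out = ndimage.gaussian_filter(np.asarray(v.voxels, dtype=np.float64), sigma_vox, mode="nearest")
    return v.with_voxels(out)


def threshold(v: Volume, t: float, direction: str = "above_or_equal") -> Mask:
    """Binary threshold: ``above_or_equal`` keeps voxels >= t, ``below`` keeps voxels < t."""
    if direction == "above_or_equal":
        m = v.voxels >= t
    elif direction == "below":
        m = v.voxels < t
    else:
        raise ValueError(f"direction must be 'below' or 'above_or_equal', got {direction!r}")
    return Mask(m.astype(np.uint8), v.spacing_mm, v.origin_mm)
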