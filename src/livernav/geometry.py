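"""Planes and signed distance fields on voxel grids.

Sign conventions (fixed throughout the package):

* sagittal plane SDF: positive toward the patient's left (+x),
* coronal plane SDF: positive anteriorly,
* axial (diaphragm) plane SDF: positive cranially (+z),
* body-surface SDF: positive outside the body, negative inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import volume as _volume

__all__ = ["Plane", "sdf_from_plane", "sdf_from_mask", "origin_point"]


@dataclass(frozen=True)
class Plane:
    """A plane in millimetre coordinates: a point on it and a unit normal.

    Both vectors are in ``(z, y, x)`` order. ``low_confidence`` marks planes
    returned from a failed refinement (initial estimate only).
    """

    point_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    low_confidence: bool = False

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("plane normal must be nonzero")
            object.__setattr__(self, "normal", tuple(n / norm))
        object.__setattr__(self, "point_mm", tuple(float(p) for p in self.point_mm))

    def signed_distance(self, points_mm) -> np.ndarray:
        """Signed distance of mm points (…, 3) to the plane."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.point_mm)) @ np.asarray(self.normal)


def sdf_from_plane(plane: Plane, grid: "_volume.Volume | _volume.Mask") -> np.ndarray:
    """Exact signed distance of every voxel centre to a plane, in mm.

    Being an affine field, it is computed in closed form:
    ``d(c) = (c - point) . normal``.
    """
    n = np.asarray(plane.normal)
    p = np.asarray(plane.point_mm)
    out = np.zeros(grid.shape, dtype=np.float64)
    # separable: d = sum_axis (origin + i*spacing - point)_axis * n_axis
    for axis in range(3):
        coord = grid.origin_mm[axis] + np.arange(grid.shape[axis]) * grid.spacing_mm[axis]
        contrib = (coord - p[axis]) * n[axis]
        shape = [1, 1, 1]
        shape[axis] = -1
        out = out + contrib.reshape(shape)
    return out


def sdf_from_mask(m: "_volume.Mask") -> np.ndarray:
    """Signed Euclidean distance (mm, anisotropy-aware) to a mask's surface.

    Positive outside, negative inside; each voxel's magnitude is the distance
    to the nearest voxel centre of the opposite class, so the zero level lies
    within half a voxel of the mask boundary.
    """
    fg = m.bool
    if not fg.any() or fg.all():
        raise ValueError("signed distance needs both foreground and background voxels")
    sampling = m.spacing_mm
    dist_to_fg = ndimage.distance_transform_edt(~fg, sampling=sampling)
    dist_to_bg = ndimage.distance_transform_edt(fg, sampling=sampling)
    return np.where(fg, -dist_to_bg, dist_to_fg)


def origin_point(planes) -> np.ndarray:
    """Intersection point (mm) of three planes, via the 3x3 linear system
    ``n_i . p = n_i . point_i``.

    Raises on near-parallel planes (condition number > 1e6).
    """
    planes = list(planes)
    if len(planes) != 3:
        raise ValueError("exactly three planes required")
    A = np.array([p.normal for p in planes], dtype=float)
    b = np.array([np.dot(p.normal, p.point_mm) for p in planes])
    if np.linalg.cond(A) > 1e6:
        raise ValueError("planes are nearly parallel; origin is degenerate")
    return np.linalg.solve(A, b)
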