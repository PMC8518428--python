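"""Synthetic CT phantoms with known anatomy for testing the whole pipeline.

The phantom is a piecewise-constant torso plus Gaussian noise: air background,
an elliptical body with a subcutaneous fat shell, a spine (vertebral column
with a posterior spinous process), rib arcs, two lungs whose inferior extent
defines the diaphragm, and six soft organs (liver, heart, spleen, stomach,
two kidneys) that all share the same mean attenuation, so that intensity
separates organ from background tissue but cannot tell the organs apart --
only position can. Approximate tissue attenuations (HU): air -1000, lung
-800, fat -100, soft tissue +30, parenchymatous organs +60, bone +500..+700.

Every structure is generated analytically from the same geometry that is
reported as ground truth, so plane and diaphragm recovery can be checked
exactly. The body can be rotated about the craniocaudal axis (``yaw_deg``)
and shifted in-plane; ground truth transforms consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import Plane
from .volume import Mask, Volume

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_probability_fixture"]

# Mean attenuation of each tissue class, HU
HU_AIR = -1000.0
HU_LUNG = -800.0
HU_FAT = -100.0
HU_TISSUE = 30.0
HU_ORGAN = 60.0
HU_SPINE = 500.0
HU_PROCESS = 700.0
HU_RIB = 600.0

FAT_THICKNESS_MM = 7.0     # subcutaneous fat shell
CHEST_WALL_MM = 5.0        # tissue between lung and fat at the lateral extreme
SPINE_RADIUS_MM = 9.0


@dataclass
class PhantomSpec:
    """Generation parameters; the seed fully determines the output."""

    shape: tuple[int, int, int] = (64, 96, 96)  # (z, y, x)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    yaw_deg: float = 0.0
    lateral_shift_mm: float | tuple[float, float] = 0.0  # x shift, or (y, x)
    noise_sd_hu: float = 15.0
    seed: int = 0
    include_liver: bool = True
    include_lungs: bool = True
    include_spine: bool = True
    #: radius multiplier for the soft organs (liver, heart, spleen). Coarse,
    #: small grids need enlarged organs for the organ voxel count to stay
    #: meaningful; anatomical proportions (1.0) leave the liver a handful of
    #: voxels at low resolution.
    organ_scale: float = 1.0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        sp = self.spacing_mm
        if np.isscalar(sp):
            sp = (sp, sp, sp)
        self.spacing_mm = tuple(float(s) for s in sp)
        if np.isscalar(self.lateral_shift_mm):
            self.lateral_shift_mm = (0.0, float(self.lateral_shift_mm))
        else:
            self.lateral_shift_mm = tuple(float(s) for s in self.lateral_shift_mm)
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.organ_scale <= 0:
            raise ValueError("organ_scale must be positive")


@dataclass
class PhantomTruth:
    """Ground-truth structures of a generated phantom."""

    body_mask: Mask
    spine_mask: Mask
    lung_mask: Mask
    liver_mask: Mask
    sagittal_plane: Plane
    coronal_plane: Plane
    diaphragm_z_mm: float


def _rotation2d(yaw_deg: float) -> np.ndarray:
    """In-plane rotation acting on (y, x) offsets."""
    a = np.deg2rad(yaw_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Build the phantom volume and its ground truth.

    Raises
    ------
    ValueError
        If the rotated/shifted body does not fit inside the grid.
    """
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing_mm
    ez, ey, ex = nz * sz, ny * sy, nx * sx  # physical extent

    # voxel-centre coordinates in mm
    z = (np.arange(nz) + 0.5)[:, None, None] * sz
    y = (np.arange(ny) + 0.5)[None, :, None] * sy
    x = (np.arange(nx) + 0.5)[None, None, :] * sx

    cy0, cx0 = ey / 2.0, ex / 2.0
    shift_y, shift_x = spec.lateral_shift_mm
    cy, cx = cy0 + shift_y, cx0 + shift_x

    # body frame: un-rotate and un-shift the in-plane coordinates, so all
    # structures are defined once in the upright, centred frame
    rot = _rotation2d(-spec.yaw_deg)
    dy = y - cy + 0.0 * x
    dx = x - cx + 0.0 * y
    u_y = rot[0, 0] * dy + rot[0, 1] * dx  # posterior offset in body frame
    u_x = rot[1, 0] * dy + rot[1, 1] * dx  # patient-left offset in body frame

    body_ry, body_rx = 0.33 * ey, 0.42 * ex
    inner_ry, inner_rx = body_ry - FAT_THICKNESS_MM, body_rx - FAT_THICKNESS_MM
    if min(inner_ry, inner_rx) <= 2 * CHEST_WALL_MM:
        raise ValueError(f"grid too small for a body phantom: extent {(ez, ey, ex)} mm")

    body = (u_y / body_ry) ** 2 + (u_x / body_rx) ** 2 <= 1.0
    body3 = np.broadcast_to(body, (nz, ny, nx))
    inner = (u_y / inner_ry) ** 2 + (u_x / inner_rx) ** 2 <= 1.0
    inner3 = np.broadcast_to(inner, (nz, ny, nx))

    # body must fit after rotation/shift: no body voxel on the in-plane border
    edge = np.zeros((ny, nx), bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if np.any(body & edge):
        raise ValueError("body does not fit inside the grid after rotation/translation")

    hu = np.full((nz, ny, nx), HU_AIR, dtype=np.float64)
    hu[body3] = HU_FAT
    hu[inner3] = HU_TISSUE

    def ellipsoid(czf, cyo, cxo, rz, ry, rx):
        """Axis-aligned (body frame) ellipsoid; centre z as fraction of ez,
        in-plane centre offsets in mm from the body centre, radii in mm."""
        return ((z - czf * ez) / rz) ** 2 + ((u_y - cyo) / ry) ** 2 + ((u_x - cxo) / rx) ** 2 <= 1.0

    # --- lungs: inferior extent defines the diaphragm ---------------------
    lung_zc, lung_rz = 0.72, 0.25 * ez
    lung_xoff = 0.55 * body_rx
    lung_yoff = -0.10 * body_ry
    # keep a CHEST_WALL_MM tissue layer between lung and fat at the widest point
    x_at = inner_rx * np.sqrt(max(1.0 - (lung_yoff / inner_ry) ** 2, 0.0))
    lung_rx = x_at - lung_xoff - CHEST_WALL_MM
    lung_ry = 0.42 * body_ry
    if lung_rx <= 2.0:
        raise ValueError("lungs do not fit inside the body")
    lung = np.zeros((nz, ny, nx), bool)
    if spec.include_lungs:
        for side in (-1.0, 1.0):
            lung |= ellipsoid(lung_zc, lung_yoff, side * lung_xoff, lung_rz, lung_ry, lung_rx)
        lung &= inner3

    # --- soft organs (same mean HU; position is the only discriminant) ----
    dia_frac = lung_zc - lung_rz / ez  # nominal diaphragm level as z fraction
    s = spec.organ_scale
    heart = ellipsoid(dia_frac + 0.125, -0.22 * body_ry, 0.12 * body_rx,
                      s * 0.13 * ez, s * 0.28 * body_ry, s * 0.24 * body_rx) & inner3
    spleen = ellipsoid(dia_frac - 0.10, 0.20 * body_ry, 0.45 * body_rx,
                       s * 0.12 * ez, s * 0.26 * body_ry, s * 0.16 * body_rx) & inner3
    stomach = ellipsoid(dia_frac - 0.12, -0.25 * body_ry, 0.10 * body_rx,
                        s * 0.10 * ez, s * 0.30 * body_ry, s * 0.22 * body_rx) & inner3
    kidneys = np.zeros((nz, ny, nx), bool)
    for side in (-1.0, 1.0):
        kidneys |= ellipsoid(dia_frac - 0.22, 0.30 * body_ry, side * 0.30 * body_rx,
                             s * 0.09 * ez, s * 0.14 * body_ry, s * 0.12 * body_rx)
    kidneys &= inner3
    confusers = heart | spleen | stomach | kidneys
    liver = np.zeros((nz, ny, nx), bool)
    if spec.include_liver:
        liver = ellipsoid(dia_frac - 0.17, -0.03 * body_ry, -0.40 * body_rx,
                          s * 0.155 * ez, s * 0.52 * body_ry, s * 0.32 * body_rx) & inner3
        # organs stay disjoint when enlarged organs touch
        liver &= ~lung & ~confusers
    hu[confusers] = HU_ORGAN
    hu[liver] = HU_ORGAN
    hu[lung] = HU_LUNG

    # --- bones: spine + spinous process + rib arcs ------------------------
    spine_yoff = 0.52 * body_ry
    spine = np.zeros((nz, ny, nx), bool)
    process = np.zeros((nz, ny, nx), bool)
    ribs = np.zeros((nz, ny, nx), bool)
    if spec.include_spine:
        spine_2d = (u_y - spine_yoff) ** 2 + u_x**2 <= SPINE_RADIUS_MM**2
        spine = np.broadcast_to(spine_2d, (nz, ny, nx)) & inner3
        proc_len = 0.35 * body_ry
        proc_2d = (np.abs(u_x) <= 2.5) & (u_y >= spine_yoff) & (u_y <= spine_yoff + proc_len)
        process = np.broadcast_to(proc_2d, (nz, ny, nx)) & inner3
        # ribs: thin elliptical shell just inside the fat, posterior-lateral
        # arcs in axial bands over the lung range (anterior and midline gaps)
        rho = np.sqrt((u_y / inner_ry) ** 2 + (u_x / inner_rx) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.degrees(np.arccos(np.clip(-u_y / np.maximum(rho * inner_ry, 1e-9), -1, 1)))
        shell_2d = (rho >= 0.88) & (rho <= 0.95) & (phi >= 45.0) & (phi <= 150.0)
        z0 = (lung_zc - lung_rz / ez) * ez
        bands = (z >= z0) & (z <= lung_zc * ez + lung_rz) & (np.mod(z - z0, 16.0) < 6.0)
        ribs = shell_2d & np.broadcast_to(bands, (nz, ny, nx)) & inner3 & ~lung
        hu[ribs] = HU_RIB
        hu[spine] = HU_SPINE
        hu[process] = HU_PROCESS

    rng = np.random.default_rng(spec.seed)
    noisy = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape) if spec.noise_sd_hu > 0 else hu

    spacing = spec.spacing_mm
    vol = Volume(noisy, spacing, (0.5 * sz, 0.5 * sy, 0.5 * sx), intensity_kind="HU")

    # --- ground truth -----------------------------------------------------
    origin = vol.origin_mm
    fwd = _rotation2d(spec.yaw_deg)
    sag_normal = np.array([0.0, fwd[0, 1], fwd[1, 1]])  # rotated +x (patient left)
    cor_normal = np.array([0.0, -fwd[0, 0], -fwd[1, 0]])  # rotated -y (anterior)
    spine_centre_in_plane = fwd @ np.array([spine_yoff, 0.0])
    sagittal = Plane(point_mm=(ez / 2.0, cy, cx), normal=tuple(sag_normal))
    coronal = Plane(
        point_mm=(ez / 2.0, cy + spine_centre_in_plane[0], cx + spine_centre_in_plane[1]),
        normal=tuple(cor_normal),
    )
    if spec.include_lungs and lung.any():
        lowest = int(np.argmax(lung.any(axis=(1, 2))))
        diaphragm_z = origin[0] + lowest * sz
    else:
        diaphragm_z = float("nan")

    def as_mask(arr):
        return Mask(np.ascontiguousarray(arr, dtype=np.uint8), spacing, origin)

    truth = PhantomTruth(
        body_mask=as_mask(body3),
        spine_mask=as_mask(spine | process),
        lung_mask=as_mask(lung),
        liver_mask=as_mask(liver),
        sagittal_plane=sagittal,
        coronal_plane=coronal,
        diaphragm_z_mm=float(diaphragm_z),
    )
    logger.debug(
        "phantom shape=%s yaw=%.1f shift=%s diaphragm_z=%.1f",
        spec.shape, spec.yaw_deg, spec.lateral_shift_mm, truth.diaphragm_z_mm,
    )
    return vol, truth


def generate_probability_fixture(
    truth: PhantomTruth,
    blob_offset_mm=(0.0, 0.0, 0.0),
    blob_radius_mm: float = 0.0,
    seed: int = 0,
) -> Volume:
    """Synthetic network-output fixture: ~0.9 on the liver, ~0.1 elsewhere,
    plus one spurious high-probability blob (for largest-component tests).

    The blob centre is ``volume centre + blob_offset_mm``; radius 0 disables it.
    """
    m = truth.liver_mask
    nzyx = np.asarray(m.shape)
    spacing = np.asarray(m.spacing_mm)
    origin = np.asarray(m.origin_mm)
    prob = np.where(m.bool, 0.9, 0.1)

    if blob_radius_mm > 0:
        centre = origin + (nzyx - 1) / 2.0 * spacing + np.asarray(blob_offset_mm, dtype=float)
        idx_centre = (centre - origin) / spacing
        if np.any(idx_centre < 0) or np.any(idx_centre > nzyx - 1):
            raise ValueError("blob lies outside the grid")
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in nzyx], indexing="ij")
        d2 = sum(((g - c) * s) ** 2 for g, c, s in zip((zz, yy, xx), idx_centre, spacing))
        prob[d2 <= blob_radius_mm**2] = 0.9

    rng = np.random.default_rng(seed)
    prob = np.clip(prob + rng.uniform(-0.05, 0.05, size=prob.shape), 0.0, 1.0)
    return Volume(prob, tuple(spacing), tuple(origin), intensity_kind="normalized")
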