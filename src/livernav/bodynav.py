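"""Body-navigation position features for CT.

The liver cannot be told apart from neighbouring parenchymatous organs by
attenuation alone; what distinguishes it is *where* it sits in the body.
This module localizes robustly segmentable structures -- the body surface,
the spine, the left-right symmetry (sagittal) plane, the coronal plane
through the spine, and the craniocaudal reference level at the top of the
diaphragm -- and converts them into four signed-distance-field channels
(sagittal, coronal, diaphragm-axial, body surface) that give every voxel a
within-body coordinate.

Pipeline (all distances and sigmas in mm; thresholds in HU):

1. resample to a coarse working resolution for speed,
2. body surface: Gaussian smooth (``SB``), threshold (``TB``), largest
   component, fill cavities,
3. spine: threshold at ``TS``, anisotropic smoothing of the bone map
   (``SS``: long sigma along the craniocaudal axis, short in-plane),
   per-slice argmax centres,
4. sagittal plane: initial estimate from the body-centre -> spine-centre
   vector, refined by minimizing the mismatch between the axial bone
   projection and its mirrored, rotated and translated copy,
5. coronal plane: through the spine centroid, perpendicular to the sagittal
   plane, oriented anteriorly,
6. diaphragm level: per-slice area of the internal cavity (below ``TLA``),
   excluding voxels near the sagittal plane (``DSA``) and near the body
   surface (``DBA``); the level is the caudal edge of the cavity band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import Plane, origin_point as _planes_origin, sdf_from_mask, sdf_from_plane
from .volume import Mask, Volume, gaussian_smooth, resample, resample_to_grid, threshold

logger = logging.getLogger(__name__)

__all__ = [
    "BodyNavParams",
    "BodyNavFeatures",
    "FeatureExtractionError",
    "segment_body",
    "localize_spine",
    "find_sagittal_plane",
    "find_coronal_plane",
    "find_diaphragm_level",
    "extract_features",
    "origin_point",
    "BodyNavExtractor",
]


class FeatureExtractionError(RuntimeError):
    """A body-navigation stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class BodyNavParams:
    """Tunable parameters of the feature extraction.

    Defaults are calibrated for abdominal CT: body smoothing ``SB`` = 3 mm
    and threshold ``TB`` = -300 HU; spine smoothing ``SS`` = 100 mm along the
    craniocaudal axis and 15 mm in-plane with bone threshold ``TS`` = 320 HU;
    internal-cavity threshold ``TLA`` = -200 HU with exclusion distances
    ``DSA`` = 30 mm (sagittal) and ``DBA`` = 1 mm (body surface).
    """

    SB: float = 3.0
    TB: float = -300.0
    SS: tuple[float, float] = (100.0, 15.0)  # (craniocaudal, in-plane) sigma, mm
    TS: float = 320.0
    TLA: float = -200.0
    DSA: float = 30.0
    DBA: float = 1.0
    working_spacing_mm: float = 4.0
    diaphragm_area_fraction: float = 0.05
    # "axial" reads the long spine sigma as in-plane instead of craniocaudal;
    # the default orientation is the one that localizes an elongated spine.
    ss_orientation: str = "craniocaudal"

    def __post_init__(self) -> None:
        if np.isscalar(self.SS):
            self.SS = (float(self.SS), float(self.SS))
        else:
            self.SS = tuple(float(s) for s in self.SS)
        for name in ("SB", "DSA", "DBA", "working_spacing_mm", "diaphragm_area_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.SS):
            raise ValueError("SS sigmas must be > 0")
        if not (self.TB < self.TLA < self.TS):
            raise ValueError(
                f"threshold ordering TB < TLA < TS violated: {self.TB}, {self.TLA}, {self.TS}"
            )
        if self.ss_orientation not in ("craniocaudal", "axial"):
            raise ValueError("ss_orientation must be 'craniocaudal' or 'axial'")

    def scaled(self, name: str, k: float) -> "BodyNavParams":
        """Copy with one parameter multiplied by ``k`` (``SS`` scales both
        sigmas; signed thresholds scale their signed HU value).

        Scaled thresholds may violate the default HU ordering on purpose --
        the sensitivity experiment must be able to run them and observe the
        resulting stage failures -- so this bypasses construction checks.
        """
        import copy

        if name not in ("SB", "TB", "SS", "TS", "TLA", "DSA", "DBA"):
            raise ValueError(f"unknown body-navigation parameter {name!r}")
        new = copy.copy(self)
        if name == "SS":
            new.SS = tuple(k * s for s in self.SS)
        else:
            setattr(new, name, k * getattr(self, name))
        return new


@dataclass
class BodyNavFeatures:
    """The four SDF channels (mm, native grid) plus the underlying geometry."""

    sdf_sagittal: np.ndarray
    sdf_coronal: np.ndarray
    sdf_axial: np.ndarray
    sdf_surface: np.ndarray
    sagittal_plane: Plane
    coronal_plane: Plane
    axial_plane: Plane
    diaphragm_z_mm: float
    cavity_area_mm2: np.ndarray  # per working-resolution slice
    body_mask: Mask  # working resolution
    spine_mask: Mask  # working resolution

    @property
    def planes(self) -> tuple[Plane, Plane, Plane]:
        return (self.sagittal_plane, self.coronal_plane, self.axial_plane)

    @property
    def channels(self) -> np.ndarray:
        """Stacked SDF channels, order (sagittal, coronal, axial, surface)."""
        return np.stack([self.sdf_sagittal, self.sdf_coronal, self.sdf_axial, self.sdf_surface])


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def segment_body(v: Volume, p: BodyNavParams | None = None) -> Mask:
    """Solid body mask: smooth, threshold, keep the largest component, and
    fill fully enclosed cavities (lungs count as inside the body)."""
    p = p or BodyNavParams()
    smoothed = gaussian_smooth(v, p.SB)
    cand = threshold(smoothed, p.TB, "above_or_equal")
    if not cand.voxels.any():
        raise FeatureExtractionError("segment_body", "no body found above threshold")
    labels, n = ndimage.label(cand.voxels)
    largest = np.argmax(ndimage.sum_labels(cand.voxels, labels, np.arange(1, n + 1))) + 1
    solid = ndimage.binary_fill_holes(labels == largest)
    return Mask(solid.astype(np.uint8), v.spacing_mm, v.origin_mm)


def localize_spine(v: Volume, p: BodyNavParams | None = None):
    """Per-slice spine centres and the overall centroid, in mm.

    The bone map (>= ``TS``) is smoothed with a strongly anisotropic Gaussian
    -- long along the craniocaudal axis, short in-plane -- which suppresses
    ribs and scattered bright voxels while reinforcing the one bony column
    that runs the length of the scan. The spine centre of each axial slice is
    the argmax of the smoothed map; the centroid averages the slice centres
    weighted by smoothed bone mass.

    Returns
    -------
    centres_mm : ndarray (nz, 3)
    centroid_mm : ndarray (3,)
    """
    p = p or BodyNavParams()
    bone = (v.voxels >= p.TS).astype(np.float64)
    if not bone.any():
        raise FeatureExtractionError("localize_spine", "no bone found above threshold")
    long_s, short_s = p.SS
    sigma_mm = (long_s, short_s, short_s) if p.ss_orientation == "craniocaudal" else (
        short_s, long_s, long_s)
    smoothed = gaussian_smooth(v.with_voxels(bone), sigma_mm).voxels

    nz = v.shape[0]
    centres = np.empty((nz, 3))
    mass = smoothed.sum(axis=(1, 2))
    for k in range(nz):
        iy, ix = np.unravel_index(np.argmax(smoothed[k]), smoothed[k].shape)
        centres[k] = v.index_to_mm((k, iy, ix))
    w = mass / mass.sum()
    centroid = (centres * w[:, None]).sum(axis=0)
    return centres, centroid


def find_sagittal_plane(
    v: Volume, body: Mask, spine_centroid_mm, p: BodyNavParams | None = None
) -> Plane:
    """Left-right symmetry plane from the axial projection of the bone map.

    The body-centre -> spine-centre vector gives the initial anteroposterior
    axis; the plane is refined by deterministic coordinate descent (golden
    section over rotation angle and lateral offset) on the mismatch between
    the projection and its reflection across the candidate axis. If the
    refinement cannot improve on the initial estimate the initial plane is
    returned flagged low-confidence.
    """
    p = p or BodyNavParams()
    bone = (v.voxels >= p.TS).astype(np.float64)
    proj = bone.sum(axis=0)

    idx = np.argwhere(body.bool)
    body_centre = (np.asarray(body.origin_mm) + idx.mean(axis=0) * np.asarray(body.spacing_mm))
    spine_c = np.asarray(spine_centroid_mm, dtype=float)

    d0 = spine_c[1:] - body_centre[1:]
    if np.linalg.norm(d0) < 1e-6:
        d0 = np.array([1.0, 0.0])  # default to the +y (posterior) axis
    d0 = d0 / np.linalg.norm(d0)
    p0 = spine_c[1:]

    ys = v.origin_mm[1] + np.arange(v.shape[1]) * v.spacing_mm[1]
    xs = v.origin_mm[2] + np.arange(v.shape[2]) * v.spacing_mm[2]
    coords = np.stack(np.meshgrid(ys, xs, indexing="ij"), axis=-1)  # (ny, nx, 2) mm

    n0 = np.array([-d0[1], d0[0]])
    pts = idx[:, 1:] * np.asarray(body.spacing_mm)[1:] + np.asarray(body.origin_mm)[1:]
    lateral = pts @ n0
    t_max = 0.25 * float(lateral.max() - lateral.min())  # 25% of body width

    def objective(theta_deg: float, t: float) -> float:
        a = np.deg2rad(theta_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        axis_dir = rot @ d0
        n = np.array([-axis_dir[1], axis_dir[0]])
        q = p0 + t * n
        dist = (coords - q) @ n
        reflected = coords - 2.0 * dist[..., None] * n
        ridx = (reflected - np.array([ys[0], xs[0]])) / np.array(
            [v.spacing_mm[1], v.spacing_mm[2]]
        )
        mirrored = ndimage.map_coordinates(
            proj, [ridx[..., 0].ravel(), ridx[..., 1].ravel()], order=1, mode="constant", cval=0.0
        ).reshape(proj.shape)
        return float(((proj - mirrored) ** 2).sum())

    def golden(fun, lo, hi, tol):
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = fun(c), fun(d)
        while (b - a) > tol:
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = fun(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = fun(d)
        return (a + b) / 2.0

    def line_min(fun, lo, hi, coarse, tol):
        """Coarse grid scan, then golden-section around the best grid point.
        The SSD is multimodal over the full range; the grid scan keeps the
        refinement in the correct valley. Fully deterministic."""
        grid = np.arange(lo, hi + 0.5 * coarse, coarse)
        best = grid[int(np.argmin([fun(g) for g in grid]))]
        return golden(fun, max(lo, best - coarse), min(hi, best + coarse), tol)

    theta, t = 0.0, 0.0
    f_init = objective(theta, t)
    for _ in range(20):
        theta_new = line_min(lambda th: objective(th, t), -20.0, 20.0, 2.0, 0.05)
        t_new = line_min(lambda tt: objective(theta_new, tt), -t_max, t_max, 2.0, 0.05)
        if abs(theta_new - theta) < 0.1 and abs(t_new - t) < 0.1:
            theta, t = theta_new, t_new
            break
        theta, t = theta_new, t_new

    low_confidence = False
    if objective(theta, t) > f_init + 1e-9:
        logger.warning("sagittal symmetry refinement failed to improve; using initial estimate")
        theta, t = 0.0, 0.0
        low_confidence = True

    a = np.deg2rad(theta)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    axis_dir = rot @ d0
    n = np.array([-axis_dir[1], axis_dir[0]])
    q = p0 + t * n
    # orient toward the patient's left (+x); fall back to +y if lateral ~ 0
    if n[1] < 0 or (abs(n[1]) < 1e-12 and n[0] < 0):
        n = -n
    zc = v.origin_mm[0] + (v.shape[0] - 1) / 2.0 * v.spacing_mm[0]
    return Plane(point_mm=(zc, q[0], q[1]), normal=(0.0, n[0], n[1]),
                 low_confidence=low_confidence)


def find_coronal_plane(sagittal: Plane, spine_centroid_mm, body_centre_mm) -> Plane:
    """Plane through the spine, perpendicular to the sagittal plane, with the
    normal oriented so the body centre (anterior of the spine) is positive."""
    z_axis = np.array([1.0, 0.0, 0.0])
    n = np.cross(z_axis, np.asarray(sagittal.normal))
    n = n / np.linalg.norm(n)
    plane = Plane(point_mm=tuple(np.asarray(spine_centroid_mm, float)), normal=tuple(n))
    d = plane.signed_distance(np.asarray(body_centre_mm, float))
    if abs(d) < 1e-9:
        raise FeatureExtractionError(
            "find_coronal_plane", "body centre lies on the coronal plane; orientation degenerate"
        )
    if d < 0:
        plane = Plane(plane.point_mm, tuple(-n))
    return plane


def find_diaphragm_level(
    v: Volume, body: Mask, sagittal: Plane, p: BodyNavParams | None = None
):
    """Craniocaudal reference level at the top of the diaphragm.

    The internal cavity (attenuation below ``TLA``, inside the body) is
    measured per axial slice, after removing voxels within ``DSA`` of the
    sagittal plane and within ``DBA`` of the body surface. The cavity band
    above the diaphragm has large area; the returned level is its caudal
    edge: starting at the curve's peak and scanning caudally, the last slice
    whose area still exceeds ``diaphragm_area_fraction`` of the maximum.

    Returns
    -------
    level_mm : float
    area_mm2 : ndarray (nz,)
    """
    p = p or BodyNavParams()
    cavity = (v.voxels < p.TLA) & body.bool
    sag_dist = sdf_from_plane(sagittal, v)
    cavity &= np.abs(sag_dist) >= p.DSA
    surface_dist = np.abs(sdf_from_mask(body))
    cavity &= surface_dist >= p.DBA

    area = cavity.sum(axis=(1, 2)) * (v.spacing_mm[1] * v.spacing_mm[2])
    if not area.any():
        raise FeatureExtractionError("find_diaphragm_level", "no internal cavity found")
    peak = int(np.argmax(area))
    cut = p.diaphragm_area_fraction * float(area.max())
    k = peak
    while k > 0 and area[k - 1] >= cut:
        k -= 1
    level_mm = v.origin_mm[0] + k * v.spacing_mm[0]
    if k > 0 and area[k] > area[k - 1]:
        # sub-slice refinement: interpolate where the area curve crosses the
        # cut, so the level does not jump by whole slices under small
        # parameter perturbations
        frac = (cut - area[k - 1]) / (area[k] - area[k - 1])
        level_mm = v.origin_mm[0] + (k - 1 + float(np.clip(frac, 0.0, 1.0))) * v.spacing_mm[0]
    return float(level_mm), area


def extract_features(v: Volume, p: BodyNavParams | None = None) -> BodyNavFeatures:
    """Run the full body-navigation pipeline and build the four SDF channels
    on the native grid of ``v`` (values in mm; normalization to [0, 1] is the
    dataset assembly's concern).

    Plane SDFs are exact affine fields evaluated analytically; the
    body-surface SDF is computed at working resolution and resampled.
    Deterministic: same volume and parameters give bit-identical output.
    """
    p = p or BodyNavParams()

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except FeatureExtractionError:
            raise
        except Exception as exc:
            raise FeatureExtractionError(name, str(exc)) from exc

    vw = stage("resample", resample, v, p.working_spacing_mm)
    body_w = segment_body(vw, p)
    _, spine_centroid = localize_spine(vw, p)
    sagittal = stage("find_sagittal_plane", find_sagittal_plane, vw, body_w, spine_centroid, p)
    idx = np.argwhere(body_w.bool)
    body_centre = np.asarray(body_w.origin_mm) + idx.mean(axis=0) * np.asarray(body_w.spacing_mm)
    coronal = find_coronal_plane(sagittal, spine_centroid, body_centre)
    level_mm, area = find_diaphragm_level(vw, body_w, sagittal, p)
    axial = Plane(point_mm=(level_mm, body_centre[1], body_centre[2]), normal=(1.0, 0.0, 0.0))

    sdf_sag = sdf_from_plane(sagittal, v)
    sdf_cor = sdf_from_plane(coronal, v)
    sdf_ax = sdf_from_plane(axial, v)
    sdf_surf_w = sdf_from_mask(body_w)
    sdf_surf = resample_to_grid(sdf_surf_w, body_w, v)

    spine_mask_w = threshold(vw, p.TS, "above_or_equal")
    return BodyNavFeatures(
        sdf_sagittal=sdf_sag,
        sdf_coronal=sdf_cor,
        sdf_axial=sdf_ax,
        sdf_surface=sdf_surf,
        sagittal_plane=sagittal,
        coronal_plane=coronal,
        axial_plane=axial,
        diaphragm_z_mm=level_mm,
        cavity_area_mm2=area,
        body_mask=body_w,
        spine_mask=spine_mask_w,
    )


def origin_point(f: BodyNavFeatures) -> np.ndarray:
    """Origin of the body coordinate system: intersection (mm) of the
    sagittal, coronal, and diaphragm-axial planes."""
    return _planes_origin(f.planes)


class BodyNavExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer from CT volumes to body-navigation features.

    Parameters mirror :class:`BodyNavParams`. ``transform`` accepts a single
    :class:`Volume` or a list of volumes (in HU) and returns
    :class:`BodyNavFeatures` correspondingly.
    """

    def __init__(
        self,
        SB: float = 3.0,
        TB: float = -300.0,
        SS: tuple[float, float] = (100.0, 15.0),
        TS: float = 320.0,
        TLA: float = -200.0,
        DSA: float = 30.0,
        DBA: float = 1.0,
        working_spacing_mm: float = 4.0,
        diaphragm_area_fraction: float = 0.05,
        ss_orientation: str = "craniocaudal",
    ):
        self.SB = SB
        self.TB = TB
        self.SS = SS
        self.TS = TS
        self.TLA = TLA
        self.DSA = DSA
        self.DBA = DBA
        self.working_spacing_mm = working_spacing_mm
        self.diaphragm_area_fraction = diaphragm_area_fraction
        self.ss_orientation = ss_orientation

    def _params(self) -> BodyNavParams:
        return BodyNavParams(**{k: getattr(self, k) for k in (
            "SB", "TB", "SS", "TS", "TLA", "DSA", "DBA",
            "working_spacing_mm", "diaphragm_area_fraction", "ss_orientation")})

    def fit(self, X=None, y=None):
        self.n_features_out_ = 4
        return self

    def transform(self, X):
        p = self._params()
        if isinstance(X, Volume):
            return extract_features(X, p)
        return [extract_features(v, p) for v in X]
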