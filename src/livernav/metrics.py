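"""Segmentation evaluation: voxel accuracy, Dice overlap, and the symmetric
surface (Hausdorff) distance MaxD in millimetres.

``MaxD = max(d(S1, S2), d(S2, S1))`` where ``d(S1, S2)`` is the largest
distance from a point of surface S1 to its nearest point on S2. Surfaces are
the centres of foreground voxels with at least one 6-neighbour background
voxel (the volume border counts as background); distances are between voxel
centres, spacing-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import Mask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "dice",
    "surface_points",
    "directed_distance",
    "maxd",
    "evaluate",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    dice: float
    maxd_mm: float  # NaN when either mask is empty (undefined, not zero)
    counts: ConfusionCounts

    @property
    def maxd_defined(self) -> bool:
        return not np.isnan(self.maxd_mm)


def _check_same_grid(pred: Mask, truth: Mask) -> None:
    if not pred.same_grid(truth):
        raise ValueError(
            f"masks are on different grids: {pred.shape}@{pred.spacing_mm} vs "
            f"{truth.shape}@{truth.spacing_mm}"
        )


def confusion(pred: Mask, truth: Mask) -> ConfusionCounts:
    """Voxelwise confusion counts of a predicted against a true mask."""
    _check_same_grid(pred, truth)
    p, t = pred.bool, truth.bool
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified voxels, (TP + TN) / total."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def dice(pred: Mask, truth: Mask) -> float:
    """Dice overlap 2|X n Y| / (|X| + |Y|); two empty masks give 1."""
    _check_same_grid(pred, truth)
    p, t = pred.bool, truth.bool
    denom = int(np.count_nonzero(p)) + int(np.count_nonzero(t))
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(p & t)) / denom


def surface_points(m: Mask) -> np.ndarray:
    """Centres (mm) of foreground voxels with a background 6-neighbour.

    The volume border counts as background, so a structure spanning the grid
    still has a closed surface.
    """
    fg = m.bool
    if not fg.any():
        raise ValueError("empty mask has no surface")
    padded = np.pad(fg, 1, mode="constant", constant_values=False)
    interior = np.ones_like(fg)
    for axis in range(3):
        lo = tuple(
            slice(0, -2) if a == axis else slice(1, -1) for a in range(3)
        )
        hi = tuple(
            slice(2, None) if a == axis else slice(1, -1) for a in range(3)
        )
        interior &= padded[lo] & padded[hi]
    surf = fg & ~interior
    idx = np.argwhere(surf)
    return np.asarray(m.origin_mm) + idx * np.asarray(m.spacing_mm)


def directed_distance(s1: np.ndarray, s2: np.ndarray) -> float:
    """max over p in S1 of the Euclidean distance to the nearest point of S2
    (mm). A KD-tree accelerates the nearest-neighbour queries; the result is
    identical to the brute-force double loop."""
    s1 = np.atleast_2d(np.asarray(s1, dtype=float))
    s2 = np.atleast_2d(np.asarray(s2, dtype=float))
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("directed distance of an empty point set is undefined")
    d, _ = cKDTree(s2).query(s1, k=1)
    return float(np.max(d))


def maxd(pred: Mask, truth: Mask) -> float:
    """Symmetric surface distance max(d(S1,S2), d(S2,S1)) in mm.

    Returns NaN (undefined) if either mask is empty.
    """
    _check_same_grid(pred, truth)
    if not pred.bool.any() or not truth.bool.any():
        return float("nan")
    s1, s2 = surface_points(pred), surface_points(truth)
    return max(directed_distance(s1, s2), directed_distance(s2, s1))


def evaluate(pred: Mask, truth: Mask) -> MetricsReport:
    """All metrics for one predicted/true mask pair."""
    c = confusion(pred, truth)
    d = 2.0 * c.TP / (2 * c.TP + c.FP + c.FN) if (2 * c.TP + c.FP + c.FN) > 0 else 1.0
    return MetricsReport(accuracy=accuracy(c), dice=d, maxd_mm=maxd(pred, truth), counts=c)


def aggregate(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Per-case table with 'Avg. value' and 'St. dev.' rows appended
    (columns: accuracy, maxd_mm, dice)."""
    rows = {
        case: {"accuracy": r.accuracy, "maxd_mm": r.maxd_mm, "dice": r.dice}
        for case, r in reports.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["Avg. value"] = df.mean()
    df.loc["St. dev."] = df.iloc[:-1].std(ddof=1) if len(rows) > 1 else 0.0
    return df
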