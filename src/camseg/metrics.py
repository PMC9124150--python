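"""Volumetric evaluation: overlap metrics, Hausdorff distance and NSD.

Overlap metrics come from voxel confusion counts:

    DSC  = 2TP / (2TP + FP + FN)        sensitivity = TP / (TP + FN)
    IOU  = TP / (TP + FP + FN)          specificity = TN / (TN + FP)
    precision = TP / (TP + FP)          accuracy    = (TP + TN) / total

Surface metrics work on surface voxels (foreground voxels with at least one
background 6-neighbour), with distances between voxel centres measured in
physical millimetres via the grid spacing.  The Hausdorff distance is the
symmetric maximum of the two directed surface-to-surface maxima; the
normalized surface distance (NSD) at tolerance tau is

    ( |{s in S_pred : d(s, S_truth) <= tau}| + |{s in S_truth : d(s, S_pred) <= tau}| )
      / ( |S_pred| + |S_truth| ),

the fraction of the two surfaces lying within tau of each other
(default tau = 4 mm).

Degenerate conventions: both masks empty -> dsc = iou = nsd = 1 and
sensitivity = 1 (perfect agreement); exactly one empty -> dsc = iou = 0 and
the Hausdorff distance is undefined (NaN or an error, per ``on_empty``).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, ShapeError
from .types import LabelMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    dsc: float
    sensitivity: float
    specificity: float
    precision: float
    iou: float
    accuracy: float
    hausdorff_mm: float  # NaN when undefined
    nsd: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _binary(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    vals = np.unique(data)
    if not set(vals.tolist()) <= {0, 1}:
        raise ShapeError(f"binary mask expected, found labels {vals.tolist()}")
    return data.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """TP/FP/TN/FN voxel tallies of a binary prediction against ground truth."""
    p, t = _binary(pred), _binary(truth)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, undefined: float) -> float:
    return num / den if den > 0 else undefined


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    """Overlap metrics from confusion counts; surface fields left NaN.

    Undefined ratios follow the degenerate conventions in the module
    docstring (empty/empty agreement scores 1).
    """
    both_empty = (c.tp + c.fp + c.fn) == 0
    return MetricReport(
        dsc=1.0 if both_empty else _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, 0.0),
        sensitivity=_ratio(c.tp, c.tp + c.fn, 1.0),
        specificity=_ratio(c.tn, c.tn + c.fp, 1.0),
        precision=_ratio(c.tp, c.tp + c.fp, 1.0 if both_empty else 0.0),
        iou=1.0 if both_empty else _ratio(c.tp, c.tp + c.fp + c.fn, 0.0),
        accuracy=_ratio(c.tp + c.tn, c.total, 1.0),
        hausdorff_mm=float("nan"),
        nsd=float("nan"),
    )


def surface_voxels(mask) -> np.ndarray:
    """Boolean array marking foreground voxels with a background 6-neighbour."""
    m = _binary(mask)
    if not m.any():
        return np.zeros_like(m)
    structure = ndimage.generate_binary_structure(m.ndim, 1)  # 6-connectivity in 3D
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return m & ~interior


def _surface_points(mask, spacing) -> np.ndarray:
    surf = surface_voxels(mask)
    idx = np.argwhere(surf)
    return idx * np.asarray(spacing, dtype=float)


def _get_spacing(mask, spacing):
    if spacing is not None:
        return spacing
    if isinstance(mask, LabelMask):
        return mask.spacing
    return (1.0, 1.0, 1.0)


def hausdorff_distance(a, b, spacing=None, on_empty: str = "error") -> float:
    """Symmetric Hausdorff distance between two mask surfaces, in mm."""
    sp_a, sp_b = _get_spacing(a, spacing), _get_spacing(b, spacing)
    pa, pb = _surface_points(a, sp_a), _surface_points(b, sp_b)
    if len(pa) == 0 or len(pb) == 0:
        if on_empty == "nan":
            return float("nan")
        raise DegenerateInputError("Hausdorff distance is undefined for an empty mask")
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def normalized_surface_distance(pred, truth, tolerance_mm: float = 4.0,
                                spacing=None) -> float:
    """Symmetric NSD: fraction of both surfaces within ``tolerance_mm``."""
    if tolerance_mm < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance_mm}")
    sp_p, sp_t = _get_spacing(pred, spacing), _get_spacing(truth, spacing)
    pp, pt = _surface_points(pred, sp_p), _surface_points(truth, sp_t)
    if len(pp) == 0 and len(pt) == 0:
        return 1.0
    if len(pp) == 0 or len(pt) == 0:
        return 0.0
    # tiny slack so voxels exactly at tolerance count as within it
    tol = tolerance_mm + 1e-9
    near_p = int(np.count_nonzero(cKDTree(pt).query(pp)[0] <= tol))
    near_t = int(np.count_nonzero(cKDTree(pp).query(pt)[0] <= tol))
    return (near_p + near_t) / (len(pp) + len(pt))


def evaluate_case(pred, truth, tolerance_mm: float = 4.0,
                  spacing=None, on_empty: str = "nan") -> MetricReport:
    """Full per-case report: overlap metrics plus Hausdorff and NSD."""
    counts = confusion_counts(pred, truth)
    report = metrics_from_counts(counts)
    report.hausdorff_mm = hausdorff_distance(pred, truth, spacing=spacing,
                                             on_empty=on_empty)
    report.nsd = normalized_surface_distance(pred, truth, tolerance_mm,
                                             spacing=spacing)
    return report
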