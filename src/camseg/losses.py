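"""Training objectives: the 2-(IOU+DSC) compound loss and dice + BCE.

Both losses use *soft* relaxations of the set overlaps: with ground truth
``y`` in {0,1} and prediction ``yhat`` in [0,1],

    |A intersect B| -> sum(y * yhat),   |A| -> sum(y),   |B| -> sum(yhat),

smoothed by ``epsilon`` in numerator and denominator so empty masks are
well-defined and gradients stay finite.  On binary ``yhat`` with
``epsilon -> 0`` the soft values coincide with the set-based DSC/IOU.

The functions are backend-generic: they accept plain numpy arrays (and
return float-valued breakdowns) or autodiff tensors (and return
differentiable breakdowns usable as training losses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .nn import autodiff as ad
from .nn.autodiff import Tensor

BCE_CLAMP = 1e-7  # yhat clamped to [BCE_CLAMP, 1 - BCE_CLAMP] inside the BCE term


@dataclass
class LossBreakdown:
    """Total loss and its additive terms (total = dice + bce + iou terms)."""

    total: object
    dice_term: object
    bce_term: object
    iou_term: object

    def totals(self) -> float:
        t = self.total
        return float(t.data) if isinstance(t, Tensor) else float(t)


def _prep(y, yhat):
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    yhat_arr = yhat.data if isinstance(yhat, Tensor) else np.asarray(yhat)
    if y_arr.shape != yhat_arr.shape:
        raise ShapeError(f"target shape {y_arr.shape} != prediction shape {yhat_arr.shape}")
    if not isinstance(y, Tensor):
        y = y_arr
    return y, yhat


def _sum(x):
    return x.sum() if isinstance(x, Tensor) else float(np.sum(x))


def _log(x):
    return ad.log(x) if isinstance(x, Tensor) else np.log(x)


def _clip(x, lo, hi):
    return ad.clip(x, lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def _scalar(x):
    return float(x.data) if isinstance(x, Tensor) else float(x)


def soft_overlap(y, yhat, epsilon: float = 1.0):
    """Soft (DSC, IOU) pair with epsilon smoothing."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    y, yhat = _prep(y, yhat)
    inter = _sum(y * yhat)
    sy = _sum(y * y) if isinstance(y, Tensor) else _sum(y)
    syh = _sum(yhat)
    dsc = (2.0 * inter + epsilon) / (sy + syh + epsilon)
    iou = (inter + epsilon) / (sy + syh - inter + epsilon)
    return dsc, iou


def loss_iou_dsc(y, yhat, epsilon: float = 1e-7) -> LossBreakdown:
    """Compound overlap loss ``2 - (IOU + DSC)``, range [0, 2].

    Zero for perfect nonempty overlap, 2 for disjoint nonempty masks.
    """
    dsc, iou = soft_overlap(y, yhat, epsilon)
    dice_term = 1.0 - dsc
    iou_term = 1.0 - iou
    total = dice_term + iou_term
    return LossBreakdown(total=total, dice_term=dice_term, bce_term=0.0, iou_term=iou_term)


def loss_dice_bce(y, yhat, epsilon: float = 1.0) -> LossBreakdown:
    """Compound loss: soft dice loss plus mean binary cross-entropy."""
    y, yhat = _prep(y, yhat)
    dsc, _ = soft_overlap(y, yhat, epsilon)
    dice_term = 1.0 - dsc
    p = _clip(yhat, BCE_CLAMP, 1.0 - BCE_CLAMP)
    n = y.data.size if isinstance(y, Tensor) else np.asarray(y).size
    bce_term = -_sum(y * _log(p) + (1.0 - y) * _log(1.0 - p)) * (1.0 / n)
    total = dice_term + bce_term
    return LossBreakdown(total=total, dice_term=dice_term, bce_term=bce_term, iou_term=0.0)


def soft_dice_score(y, yhat, epsilon: float = 1.0) -> float:
    """Convenience: scalar soft DSC of a prediction against a binary target."""
    dsc, _ = soft_overlap(np.asarray(y, dtype=np.float64),
                          yhat if isinstance(yhat, Tensor) else np.asarray(yhat), epsilon)
    return _scalar(dsc)
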