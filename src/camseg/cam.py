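"""Channel attention module (CAM) for cross-level feature fusion.

The block fuses a *low-level* feature map ``X_L`` (fine spatial detail, from
an encoder stage) with a *high-level* map ``X_H`` (coarse but semantically
rich, from a deeper decoder stage):

1. ``X_L' = conv3(X_L)`` — a same-padded 3x3(x3) convolution aligning the
   low-level channel count with the high-level one,
2. ``g = GAP(X_H)`` — global average pooling of the high-level map into one
   scalar per channel,
3. ``X_gL[k] = conv1(X_L')[k] * g[k]`` — a 1x1(x1) convolution followed by
   per-channel scalar gating: each low-level channel is scaled by how active
   the corresponding high-level channel is globally,
4. ``X_cam = X_gL + up(X_H)`` — additive fusion with the bi/tri-linearly
   upsampled high-level map at the low-level resolution.

No squashing nonlinearity is applied to the pooled gate vector by default
(``gate_activation="none"``); a sigmoid variant is available.

This module is the *functional* (numpy, inference-only) form used in tests
and analysis; :class:`CAMBlock` is the trainable twin that lives inside the
network graph and shares exactly this arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv, Module


@dataclass
class FeatureMap:
    """A ``(channels, *spatial)`` real array; spatial part is 2D or 3D."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (3, 4):
            raise ShapeError(
                f"FeatureMap must be (channels, *spatial) with 2D or 3D spatial part, "
                f"got ndim={self.values.ndim}")
        if self.values.shape[0] < 1:
            raise ShapeError("FeatureMap needs at least one channel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[1:]


@dataclass
class CAMParams:
    """Kernel banks of the CAM block.

    ``conv3_weights``: ``(c_H, c_L, 3[,3],3)`` same-padded bank;
    ``conv1_weights``: ``(c_H, c_H, 1[,1],1)`` pointwise bank.
    """

    conv3_weights: np.ndarray
    conv3_bias: np.ndarray
    conv1_weights: np.ndarray
    conv1_bias: np.ndarray
    gate_activation: str = "none"  # {"none", "sigmoid"}

    def __post_init__(self) -> None:
        self.conv3_weights = np.asarray(self.conv3_weights, dtype=np.float64)
        self.conv1_weights = np.asarray(self.conv1_weights, dtype=np.float64)
        self.conv3_bias = np.asarray(self.conv3_bias, dtype=np.float64)
        self.conv1_bias = np.asarray(self.conv1_bias, dtype=np.float64)
        c_h = self.conv3_weights.shape[0]
        if self.conv1_weights.shape[:2] != (c_h, c_h):
            raise ShapeError(
                f"conv1 bank must map {c_h}->{c_h} channels, got {self.conv1_weights.shape[:2]}")
        if self.conv3_bias.shape != (c_h,) or self.conv1_bias.shape != (c_h,):
            raise ShapeError("bias shapes must equal the output channel count")
        if self.gate_activation not in ("none", "sigmoid"):
            raise ValueError(f"unknown gate_activation {self.gate_activation!r}")

    @classmethod
    def initialize(cls, c_l: int, c_h: int, spatial_dims: int,
                   rng: np.random.Generator, gate_activation: str = "none") -> "CAMParams":
        k3 = (c_h, c_l) + (3,) * spatial_dims
        k1 = (c_h, c_h) + (1,) * spatial_dims
        s3 = np.sqrt(2.0 / (c_l * 3 ** spatial_dims))
        s1 = np.sqrt(2.0 / c_h)
        return cls(rng.normal(0, s3, k3), np.zeros(c_h),
                   rng.normal(0, s1, k1), np.zeros(c_h), gate_activation)

    @classmethod
    def identity(cls, c: int, spatial_dims: int) -> "CAMParams":
        """Center-tap-one kernels: conv3 and conv1 both act as the identity."""
        k3 = np.zeros((c, c) + (3,) * spatial_dims)
        center = (1,) * spatial_dims
        for i in range(c):
            k3[(i, i) + center] = 1.0
        k1 = np.eye(c).reshape((c, c) + (1,) * spatial_dims)
        return cls(k3, np.zeros(c), k1, np.zeros(c))


def _np_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ad.conv(Tensor(x), Tensor(w), Tensor(b), padding="same").data


def global_avg_pool(x_h: FeatureMap) -> np.ndarray:
    """Per-channel arithmetic mean over all spatial positions of ``X_H``."""
    if x_h.values.shape[1:] == () or 0 in x_h.values.shape:
        raise ShapeError("cannot pool a feature map with empty spatial extent")
    return x_h.values.mean(axis=tuple(range(1, x_h.values.ndim)))


def upsample_to(x_h: FeatureMap, target_spatial_shape: tuple[int, ...]) -> FeatureMap:
    """Bi/tri-linear upsampling of the high-level map to the low-level grid."""
    for s, t in zip(x_h.spatial_shape, target_spatial_shape):
        if t < s:
            raise ShapeError(
                f"upsample target {target_spatial_shape} is smaller than input "
                f"{x_h.spatial_shape}; downsampling is not part of the fusion")
    out = ad.upsample_linear(Tensor(x_h.values), tuple(target_spatial_shape)).data
    return FeatureMap(out)


def low_level_transform(x_l: FeatureMap, params: CAMParams) -> FeatureMap:
    """``X_L' = conv3(X_L)``: channel alignment of the low-level map."""
    if x_l.channels != params.conv3_weights.shape[1]:
        raise ShapeError(
            f"low-level map has {x_l.channels} channels, conv3 expects "
            f"{params.conv3_weights.shape[1]}")
    return FeatureMap(_np_conv(x_l.values, params.conv3_weights, params.conv3_bias))


def channel_gate(x_lp: FeatureMap, g: np.ndarray, params: CAMParams) -> FeatureMap:
    """``X_gL[k] = conv1(X_L')[k] * g[k]``: per-channel scalar gating."""
    g = np.asarray(g, dtype=np.float64)
    c = params.conv1_weights.shape[1]
    if x_lp.channels != c or g.shape != (params.conv1_weights.shape[0],):
        raise ShapeError(
            f"channel_gate needs {c}-channel input and a length-{params.conv1_weights.shape[0]} "
            f"gate vector; got {x_lp.channels} channels and gate shape {g.shape}")
    if params.gate_activation == "sigmoid":
        g = 1.0 / (1.0 + np.exp(-g))
    gated = _np_conv(x_lp.values, params.conv1_weights, params.conv1_bias)
    nd = gated.ndim - 1
    return FeatureMap(gated * g.reshape((-1,) + (1,) * nd))


def cam_fuse(x_l: FeatureMap, x_h: FeatureMap, params: CAMParams) -> FeatureMap:
    """Full CAM fusion: gated low-level map plus upsampled high-level map."""
    if x_l.values.ndim != x_h.values.ndim:
        raise ShapeError("low- and high-level maps must share spatial dimensionality")
    for lo, hi in zip(x_l.spatial_shape, x_h.spatial_shape):
        if lo < hi:
            raise ShapeError(
                f"low-level spatial shape {x_l.spatial_shape} must be >= high-level "
                f"{x_h.spatial_shape} on every axis")
    gate = global_avg_pool(x_h)
    x_lp = low_level_transform(x_l, params)
    x_gl = channel_gate(x_lp, gate, params)
    up = upsample_to(x_h, x_l.spatial_shape)
    return FeatureMap(x_gl.values + up.values)


class CAMBlock(Module):
    """Trainable CAM block used on SegChaNet skip connections.

    Implements the same composition as :func:`cam_fuse` with autodiff
    tensors so the kernel banks are learned end to end.
    """

    def __init__(self, c_l: int, c_h: int, spatial_dims: int,
                 rng: np.random.Generator, gate_activation: str = "none"):
        self.conv3 = Conv(c_l, c_h, 3, spatial_dims, rng)
        self.conv1 = Conv(c_h, c_h, 1, spatial_dims, rng)
        self.gate_activation = gate_activation

    def __call__(self, x_l: Tensor, x_h: Tensor) -> Tensor:
        gate = ad.global_avg_pool(x_h, keepdims=True)
        if self.gate_activation == "sigmoid":
            gate = ad.sigmoid(gate)
        gated = self.conv1(self.conv3(x_l)) * gate
        up = ad.upsample_linear(x_h, x_l.data.shape[1:])
        return gated + up

    def export_params(self) -> CAMParams:
        """Snapshot the kernels as functional :class:`CAMParams`."""
        return CAMParams(self.conv3.weight.data, self.conv3.bias.data,
                         self.conv1.weight.data, self.conv1.bias.data,
                         self.gate_activation)
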