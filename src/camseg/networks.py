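"""Encoder-decoder segmentation architectures: U-Net, V-Net and SegChaNet.

All three map a ``(in_channels, *spatial)`` volume to a per-voxel
probability map of the same spatial shape.  Convolutions are same-padded
throughout so skip connections and the CAM fusion type-check without
cropping.  SegChaNet is the channel-attention network: four (configurable)
encoder/decoder blocks of conv-BN-leakyReLU pairs, 3D max-pool
downsampling, a sequential dilated-convolution stack at the bottleneck
whose dilation rate doubles layer by layer, 2x-upsampling decoders, and a
CAM block on each encoder-to-decoder skip connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cam import CAMBlock
from .errors import ConfigError, ShapeError
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import BatchNorm, Conv, Module
from .types import CTVolume, LabelMask


@dataclass
class NetworkConfig:
    """All architecture tunables.

    ``depth`` counts encoder (= decoder) resolution levels; SegChaNet's
    default is 4, V-Net's published form uses 6.  ``dilation_schedule``
    doubles from 1 by default, matching the bottleneck design.
    """

    spatial_dims: int = 3
    in_channels: int = 1
    n_classes: int = 1
    depth: int = 4
    base_channels: int = 8
    channel_growth: int = 2
    use_cam: bool = True
    cam_levels: tuple[int, ...] | None = None  # None = every skip level
    dilation_schedule: tuple[int, ...] = (1, 2, 4)
    leaky_relu_slope: float = 0.01
    output_activation: str = "sigmoid"  # {"sigmoid", "softmax"}
    deep_supervision: bool = False
    gate_activation: str = "none"
    # sigmoid-head bias prior: tumor voxels are a tiny fraction of a scan, so
    # the head starts near the foreground prevalence (~0.25%) instead of 0.5
    head_bias_init: float = -6.0

    def __post_init__(self) -> None:
        if self.spatial_dims not in (2, 3):
            raise ConfigError("spatial_dims must be 2 or 3")
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.output_activation not in ("sigmoid", "softmax"):
            raise ConfigError(f"unknown output_activation {self.output_activation!r}")
        if any(d < 1 for d in self.dilation_schedule):
            raise ConfigError("dilation rates must be >= 1")

    @property
    def widths(self) -> list[int]:
        return [self.base_channels * self.channel_growth ** i for i in range(self.depth)]

    @property
    def out_channels(self) -> int:
        return self.n_classes if self.output_activation == "softmax" else max(self.n_classes, 1)


def _check_input(x: np.ndarray, cfg: NetworkConfig, divisor: int) -> None:
    if x.ndim != cfg.spatial_dims + 1 or x.shape[0] != cfg.in_channels:
        raise ShapeError(
            f"expected ({cfg.in_channels}, *spatial) with {cfg.spatial_dims}D spatial part, "
            f"got shape {x.shape}")
    for s in x.shape[1:]:
        if s < 2 ** cfg.depth:
            raise ShapeError(f"input extent {s} smaller than 2^depth = {2 ** cfg.depth}")
        if s % divisor:
            raise ShapeError(f"input extent {s} not divisible by {divisor}")


class _ConvAct(Module):
    """conv (+ optional BN) + ReLU/leaky-ReLU."""

    def __init__(self, cin: int, cout: int, nd: int, rng, *, slope: float = 0.0,
                 dilation: int = 1, norm: bool = False):
        self.conv = Conv(cin, cout, 3, nd, rng, dilation=dilation)
        self.bn = BatchNorm(cout) if norm else None
        self.slope = slope

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.conv(x)
        if self.bn is not None:
            h = self.bn(h, training)
        return ad.leaky_relu(h, self.slope) if self.slope else ad.relu(h)


class _Stack(Module):
    def __init__(self, blocks: list[Module]):
        self.blocks = blocks

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        for blk in self.blocks:
            x = blk(x, training)
        return x


class SegmentationNetwork(Module):
    """Common surface: ``forward``, activation recording, parameter count."""

    config: NetworkConfig

    def forward(self, x, training: bool = False, record: bool = False) -> Tensor:
        raise NotImplementedError

    @property
    def activations(self) -> dict[str, Tensor]:
        return getattr(self, "_activations", {})


class UNet(SegmentationNetwork):
    """Contracting/expanding path with max pooling, skip concatenation,
    channel doubling and a sigmoid head."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.config = cfg
        nd, w = cfg.spatial_dims, cfg.widths
        self.enc = [
            _Stack([_ConvAct(cfg.in_channels if i == 0 else w[i - 1], w[i], nd, rng),
                    _ConvAct(w[i], w[i], nd, rng)])
            for i in range(cfg.depth)
        ]
        self.dec = [
            _Stack([_ConvAct(w[i] + w[i + 1], w[i], nd, rng),
                    _ConvAct(w[i], w[i], nd, rng)])
            for i in range(cfg.depth - 1)
        ]
        self.head = Conv(w[0], cfg.out_channels, 1, nd, rng)
        if cfg.output_activation == "sigmoid":
            self.head.bias.data[:] = cfg.head_bias_init

    def forward(self, x, training: bool = False, record: bool = False) -> Tensor:
        cfg = self.config
        x = ad.as_tensor(x)
        _check_input(x.data, cfg, 2 ** cfg.depth)
        acts: dict[str, Tensor] = {}
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk(h, training)
            acts[f"enc{i}"] = h
            if i < cfg.depth - 1:
                skips.append(h)
                h = ad.max_pool(h)
        for i in range(cfg.depth - 2, -1, -1):
            h = ad.upsample_nearest(h)
            h = ad.concat([skips[i], h], axis=0)
            h = self.dec[i](h, training)
            acts[f"dec{i}"] = h
        out = _apply_head(self.head(h), cfg)
        if record:
            self._activations = acts
        return out


class _ResStage(Module):
    """x + branch(x); zeroing the branch convolutions makes it the identity."""

    def __init__(self, ch: int, nd: int, rng):
        self.pre = _ConvAct(ch, ch, nd, rng, norm=True)
        self.post = Conv(ch, ch, 3, nd, rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return x + self.post(self.pre(x, training))


class VNet(SegmentationNetwork):
    """Residual stages with strided-convolution downsampling (no pooling),
    additive skips, and a 1x1x1 convolution + softmax head."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        if cfg.spatial_dims != 3:
            raise ConfigError("V-Net is a volumetric (3D) architecture")
        self.config = cfg
        nd = cfg.spatial_dims
        w = [cfg.base_channels * cfg.channel_growth ** i for i in range(cfg.depth + 1)]
        self.stem = Conv(cfg.in_channels, w[0], 3, nd, rng)
        self.enc = [_ResStage(w[i], nd, rng) for i in range(cfg.depth)]
        self.down = [Conv(w[i], w[i + 1], 2, nd, rng, stride=2, padding="valid")
                     for i in range(cfg.depth)]
        self.bottom = _ResStage(w[cfg.depth], nd, rng)
        self.up = [Conv(w[i + 1], w[i], 3, nd, rng) for i in range(cfg.depth)]
        self.dec = [_ResStage(w[i], nd, rng) for i in range(cfg.depth)]
        n_out = max(cfg.n_classes, 2)  # softmax needs at least two classes
        self.head = Conv(w[0], n_out, 1, nd, rng)

    def forward(self, x, training: bool = False, record: bool = False) -> Tensor:
        cfg = self.config
        x = ad.as_tensor(x)
        _check_input(x.data, cfg, 2 ** cfg.depth)
        acts: dict[str, Tensor] = {}
        h = self.stem(x)
        skips = []
        for i in range(cfg.depth):
            h = self.enc[i](h, training)
            acts[f"enc{i}"] = h
            skips.append(h)
            h = self.down[i](h)
        h = self.bottom(h, training)
        acts["bottleneck"] = h
        for i in range(cfg.depth - 1, -1, -1):
            h = self.up[i](ad.upsample_nearest(h))
            h = h + skips[i]
            h = self.dec[i](h, training)
            acts[f"dec{i}"] = h
        out = ad.softmax(self.head(h), axis=0)
        if record:
            self._activations = acts
        return out


class SegChaNet(SegmentationNetwork):
    """The channel-attention encoder-decoder network (see module docstring)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.config = cfg
        nd, w = cfg.spatial_dims, cfg.widths
        slope = cfg.leaky_relu_slope
        self.enc = [
            _Stack([_ConvAct(cfg.in_channels if i == 0 else w[i - 1], w[i], nd, rng,
                             slope=slope, norm=True),
                    _ConvAct(w[i], w[i], nd, rng, slope=slope, norm=True)])
            for i in range(cfg.depth)
        ]
        deep = w[cfg.depth - 1]
        self.bottleneck = _Stack([
            _ConvAct(deep, deep, nd, rng, slope=slope, dilation=d, norm=True)
            for d in cfg.dilation_schedule
        ])
        cam_levels = set(range(cfg.depth - 1)) if cfg.cam_levels is None \
            else set(cfg.cam_levels)
        self.cam_blocks: list[Module | None] = []
        self.dec = []
        for i in range(cfg.depth - 1):
            if cfg.use_cam and i in cam_levels:
                self.cam_blocks.append(
                    CAMBlock(w[i], w[i + 1], nd, rng, cfg.gate_activation))
                dec_in = w[i + 1]
            else:
                self.cam_blocks.append(None)
                dec_in = w[i] + w[i + 1]
            self.dec.append(_Stack([
                _ConvAct(dec_in, w[i], nd, rng, slope=slope, norm=True),
                _ConvAct(w[i], w[i], nd, rng, slope=slope, norm=True)]))
        head_in = sum(w[:cfg.depth - 1]) if cfg.deep_supervision else w[0]
        self.head = Conv(head_in, cfg.out_channels, 1, nd, rng)
        if cfg.output_activation == "sigmoid":
            self.head.bias.data[:] = cfg.head_bias_init

    def _check_receptive_field(self, deepest: tuple[int, ...]) -> None:
        rf = 1 + 2 * sum(self.config.dilation_schedule)
        if rf > min(deepest):
            raise ShapeError(
                f"dilation stack receptive field {rf} exceeds the deepest feature map "
                f"{deepest}; shorten dilation_schedule or reduce depth")

    def forward(self, x, training: bool = False, record: bool = False) -> Tensor:
        cfg = self.config
        x = ad.as_tensor(x)
        _check_input(x.data, cfg, 2 ** cfg.depth)
        full = x.data.shape[1:]
        self._check_receptive_field(tuple(s // 2 ** (cfg.depth - 1) for s in full))
        acts: dict[str, Tensor] = {}
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk(h, training)
            acts[f"enc{i}"] = h
            if i < cfg.depth - 1:
                skips.append(h)
                h = ad.max_pool(h)
        h = self.bottleneck(h, training)
        acts["bottleneck"] = h
        dec_outputs = []
        for i in range(cfg.depth - 2, -1, -1):
            cam = self.cam_blocks[i]
            if cam is not None:
                h = cam(skips[i], h)
            else:
                h = ad.concat([skips[i], ad.upsample_nearest(h)], axis=0)
            h = self.dec[i](h, training)
            acts[f"dec{i}"] = h
            dec_outputs.append(h)
        if cfg.deep_supervision:
            scaled = [ad.upsample_linear(d, full) if d.data.shape[1:] != full else d
                      for d in dec_outputs]
            h = ad.concat(scaled, axis=0)
        out = _apply_head(self.head(h), cfg)
        if record:
            self._activations = acts
        return out


def _apply_head(logits: Tensor, cfg: NetworkConfig) -> Tensor:
    if cfg.output_activation == "softmax":
        return ad.softmax(logits, axis=0)
    return ad.sigmoid(logits)


def build_unet(cfg: NetworkConfig, seed: int = 0) -> UNet:
    return UNet(cfg, np.random.default_rng(seed))


def build_vnet(cfg: NetworkConfig, seed: int = 0) -> VNet:
    return VNet(cfg, np.random.default_rng(seed))


def build_segchanet(cfg: NetworkConfig, seed: int = 0) -> SegChaNet:
    return SegChaNet(cfg, np.random.default_rng(seed))


def forward(net: SegmentationNetwork, vol) -> np.ndarray:
    """Inference: run a preprocessed volume through ``net``.

    Accepts a :class:`CTVolume` or a bare array (with or without the channel
    axis); returns the probability map as ``(channels, *spatial)`` numpy.
    """
    data = vol.data if isinstance(vol, CTVolume) else np.asarray(vol)
    if data.ndim == net.config.spatial_dims:
        data = data[None]
    out = net.forward(Tensor(data.astype(np.float32)), training=False)
    return out.data


def predict_mask(prob: np.ndarray, threshold: float = 0.5,
                 like: CTVolume | None = None) -> LabelMask:
    """Binarize a probability map: voxel = 1 iff ``prob > threshold``.

    The tie ``prob == threshold`` maps to background (strict inequality),
    fixed for reproducibility.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    prob = np.asarray(prob)
    if prob.ndim == 4:
        if prob.shape[0] == 1:
            prob = prob[0]
        else:  # softmax map: foreground = class 1
            prob = prob[1]
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    data = (prob > threshold).astype(np.int16)
    if like is not None:
        return LabelMask(data, spacing=like.spacing, origin=like.origin,
                         direction=like.direction)
    return LabelMask(data)
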