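"""Trainable layers built on the autodiff core.

A :class:`Module` owns :class:`Parameter` leaves (discovered recursively
through attributes, lists and dicts) and exposes ``parameters()`` /
``named_parameters()`` plus flat ``state_dict``-style (de)serialisation for
checkpoints.  Layers take an explicit ``training`` flag instead of global
mode state.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def _children(self) -> Iterator[tuple[str, object]]:
        for name, value in vars(self).items():
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, child in self._children():
            full = f"{prefix}{name}"
            if isinstance(child, Parameter):
                yield full, child
            else:
                yield from child.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # checkpoint support -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value, dtype=params[key].data.dtype)
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.named_buffers(prefix=f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{prefix}{name}.{i}.")
        for name in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{name}", getattr(self, name)


class Conv(Module):
    """Same- or valid-padded N-D convolution with He-normal init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 spatial_dims: int, rng: np.random.Generator, *, stride: int = 1,
                 dilation: int = 1, padding: str = "same", bias: bool = True):
        kshape = (out_channels, in_channels) + (kernel_size,) * spatial_dims
        fan_in = in_channels * kernel_size ** spatial_dims
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, size=kshape))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.dilation = dilation
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv(x, self.weight, self.bias, stride=self.stride,
                       dilation=self.dilation, padding=self.padding)


class BatchNorm(Module):
    """Per-channel normalization over spatial locations.

    Statistics are computed per sample (cases are fed one at a time and
    minibatches formed by gradient accumulation); exponential running
    averages are used at inference.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        nd = x.data.ndim - 1
        shape = (-1,) + (1,) * nd
        if training:
            axes = tuple(range(1, x.data.ndim))
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            # mean/var treated as functions of x: full batch-norm backward
            xhat = _normalize(x, mean, var, self.eps)
        else:
            dt = x.data.dtype
            xhat = (x - self.running_mean.reshape(shape).astype(dt)) * (
                (self.running_var + self.eps) ** -0.5).reshape(shape).astype(dt)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


def _normalize(x: Tensor, mean: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    """x-hat with the exact batch-norm gradient (mean/var depend on x)."""
    nd = x.data.ndim - 1
    shape = (-1,) + (1,) * nd
    inv = ((var + eps) ** -0.5).reshape(shape)
    xhat = (x.data - mean.reshape(shape)) * inv
    n = int(np.prod(x.data.shape[1:]))
    axes = tuple(range(1, x.data.ndim))

    def back(g):
        gsum = g.sum(axis=axes, keepdims=True)
        gx_dot = (g * xhat).sum(axis=axes, keepdims=True)
        return inv * (g - gsum / n - xhat * gx_dot / n)

    return Tensor(xhat.astype(x.data.dtype, copy=False), parents=[(x, back)])
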