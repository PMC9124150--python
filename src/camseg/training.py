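"""Training protocol: Adam + plateau schedule, hyperparameter grid,
k-fold majority-vote ensembling and grad-CAM saliency.

The optimisation schedule: Adam at an initial learning rate (default
5e-4), monitoring validation binary cross-entropy; if the monitored value
does not improve for ``lr_patience`` epochs (default 15) the learning rate
is multiplied by ``lr_factor`` (default 0.1).  The learning-rate trajectory
is therefore non-increasing and piecewise constant.  Minibatches are formed
by gradient accumulation over cases; all randomness (shuffling,
augmentation) flows from one seed so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses as L
from .errors import ConfigError, ShapeError
from .networks import (NetworkConfig, SegmentationNetwork, build_segchanet,
                       build_unet, build_vnet, forward)
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.optim import Adam
from .phantoms import PhantomCase
from .types import CTVolume, LabelMask


@dataclass
class TrainConfig:
    initial_lr: float = 5e-4
    minibatch: int = 2
    epochs: int = 500
    lr_factor: float = 0.1
    lr_patience: int = 15
    monitor: str = "val_bce"
    folds: int = 5
    seed: int = 0
    loss: str = "eq6"  # {"eq1": 2-(IOU+DSC), "eq6": dice + BCE}

    def __post_init__(self) -> None:
        if not 0 < self.lr_factor < 1:
            raise ConfigError("lr_factor must be in (0, 1)")
        if self.minibatch < 1:
            raise ConfigError("minibatch must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.loss not in ("eq1", "eq6"):
            raise ConfigError(f"loss must be 'eq1' or 'eq6', got {self.loss!r}")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)
        lrs = [r["lr"] for r in self.records]
        if any(b > a + 1e-15 for a, b in zip(lrs, lrs[1:])):
            raise ValueError("learning rate must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def final(self) -> dict:
        return self.records[-1] if self.records else {}


def _as_xy(case) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a case to (x: (1, *spatial) float32, y: (*spatial) float64)."""
    if isinstance(case, PhantomCase):
        vol, mask = case.volume, case.mask
    else:
        vol, mask = case
    x = vol.data if isinstance(vol, CTVolume) else np.asarray(vol)
    y = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    if x.ndim == y.ndim:
        x = x[None]
    return x.astype(np.float32), y.astype(np.float64)


def _case_loss(net: SegmentationNetwork, x, y, loss_name: str, training: bool):
    out = net.forward(Tensor(x), training=training)
    target = y[None] if out.data.ndim == y.ndim + 1 and out.data.shape[0] == 1 else y
    if loss_name == "eq1":
        return L.loss_iou_dsc(target, out, epsilon=1.0), out
    return L.loss_dice_bce(target, out), out


def train_model(net: SegmentationNetwork, dataset, cfg: TrainConfig,
                val_dataset=None, augment_fn=None
                ) -> tuple[SegmentationNetwork, TrainHistory]:
    """Train ``net`` on preprocessed cases; returns the net and its history.

    ``dataset`` / ``val_dataset`` are sequences of (volume, mask) pairs or
    :class:`PhantomCase`; ``augment_fn(x, y, seed) -> (x, y)`` is applied to
    *training* cases only.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    cases = [_as_xy(c) for c in dataset]
    shapes = {c[0].shape for c in cases}
    if len(shapes) > 1:
        raise ShapeError(f"all cases must share one shape, got {sorted(shapes)}")
    val_cases = [_as_xy(c) for c in val_dataset] if val_dataset else None

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.initial_lr)
    history = TrainHistory()
    best = np.inf
    since = 0
    lr = cfg.initial_lr
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(cases))
        epoch_losses = []
        opt.zero_grad()
        pending = 0
        for j, idx in enumerate(order):
            x, y = cases[idx]
            if augment_fn is not None:
                x, y = augment_fn(x, y, int(rng.integers(2 ** 31 - 1)))
            breakdown, _ = _case_loss(net, x, y, cfg.loss, training=True)
            scale = 1.0 / min(cfg.minibatch, len(cases))
            (breakdown.total * scale).backward()
            epoch_losses.append(breakdown.totals())
            pending += 1
            if pending == cfg.minibatch or j == len(order) - 1:
                opt.step()
                opt.zero_grad()
                pending = 0
        train_loss = float(np.mean(epoch_losses))
        val_loss = None
        if val_cases:
            vals = []
            for x, y in val_cases:
                breakdown, _ = _case_loss(net, x, y, "eq6", training=False)
                vals.append(L._scalar(breakdown.bce_term))
            val_loss = float(np.mean(vals))  # monitored metric: validation BCE
        monitored = val_loss if val_loss is not None else train_loss
        if monitored < best:
            best = monitored
            since = 0
        else:
            since += 1
            if since >= cfg.lr_patience:
                lr *= cfg.lr_factor
                opt.lr = lr
                since = 0
        history.append(epoch=epoch, train_loss=train_loss, val_loss=val_loss, lr=lr)
    return net, history


def reduce_lr_on_plateau(history: TrainHistory, cfg: TrainConfig) -> float:
    """Replay the plateau rule over a history; returns the resulting rate.

    Each epoch whose monitored value fails to improve on the running best
    increments a counter; at ``lr_patience`` the rate is multiplied by
    ``lr_factor`` and the counter resets.  The rate never increases.
    """
    if not history.records:
        raise ValueError("history must be non-empty")
    lr = cfg.initial_lr
    best = np.inf
    since = 0
    for rec in history.records:
        v = rec.get("val_loss")
        if v is None:
            v = rec["train_loss"]
        if v < best:
            best = v
            since = 0
        else:
            since += 1
            if since >= cfg.lr_patience:
                lr *= cfg.lr_factor
                since = 0
    return lr


def run_hyperparameter_grid(dataset, grid, net_cfg: NetworkConfig,
                            base_cfg: TrainConfig, val_dataset=None,
                            builder=build_segchanet) -> pd.DataFrame:
    """One training run per (initial_lr, minibatch) row; table of outcomes.

    The published search grid is nine rows; `best` is the row maximising
    validation soft-DSC (falling back to the training set when no
    validation cases are given).
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    eval_cases = val_dataset if val_dataset else dataset
    for run_id, (ilr, mb) in enumerate(grid):
        cfg = TrainConfig(**{**asdict(base_cfg), "initial_lr": float(ilr),
                             "minibatch": int(mb)})
        net = builder(net_cfg, seed=cfg.seed)
        net, history = train_model(net, dataset, cfg, val_dataset=val_dataset)
        dscs = []
        for case in eval_cases:
            x, y = _as_xy(case)
            prob = forward(net, x)
            dscs.append(L.soft_dice_score(y, prob.squeeze(0) if prob.shape[0] == 1 else prob))
        rows.append({"run": run_id + 1, "initial_lr": float(ilr), "minibatch": int(mb),
                     "final_train_loss": history.final["train_loss"],
                     "final_val_loss": history.final["val_loss"],
                     "val_dsc": float(np.mean(dscs))})
    table = pd.DataFrame(rows)
    table.attrs["best_run"] = int(table.loc[table.val_dsc.idxmax(), "run"])
    return table


def kfold_split(n_cases: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic partition of case indices into ``folds`` validation folds."""
    if folds < 2 or folds > n_cases:
        raise ValueError(f"need 2 <= folds <= n_cases, got folds={folds}, n={n_cases}")
    order = np.random.default_rng(seed).permutation(n_cases)
    return [np.sort(order[i::folds]) for i in range(folds)]


def ensemble_majority_vote(masks) -> LabelMask:
    """Per-voxel majority vote over an odd number of binary masks."""
    if len(masks) % 2 == 0:
        raise ValueError(f"majority vote needs an odd member count, got {len(masks)}")
    first = masks[0]
    arrays = [m.data if isinstance(m, LabelMask) else np.asarray(m) for m in masks]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ShapeError(f"all members must share one shape, got {sorted(shapes)}")
    for a in arrays:
        if not set(np.unique(a).tolist()) <= {0, 1}:
            raise ValueError("majority vote is defined on binary masks")
    votes = np.sum(arrays, axis=0)
    data = (votes > len(arrays) / 2).astype(np.int16)
    if isinstance(first, LabelMask):
        return first.with_data(data)
    if data.ndim != 3:
        raise ShapeError("plain-array members must be 3D")
    return LabelMask(data)


def gradcam_heatmap(net: SegmentationNetwork, vol, target_layer: str) -> np.ndarray:
    """Gradient-weighted channel pooling at ``target_layer``.

    The foreground score (sum of predicted foreground probability) is
    backpropagated to the chosen layer; channels are pooled with the
    spatial mean of their gradients, passed through ReLU and max-normalised
    to 1, then upsampled to input resolution.
    """
    data = vol.data if isinstance(vol, CTVolume) else np.asarray(vol)
    if data.ndim == net.config.spatial_dims:
        data = data[None]
    x = data.astype(np.float32)
    out = net.forward(Tensor(x), training=False, record=True)
    acts = net.activations
    if target_layer not in acts:
        raise KeyError(
            f"unknown layer {target_layer!r}; available: {sorted(acts)}")
    seed = np.zeros_like(out.data)
    if net.config.output_activation == "softmax":
        seed[min(out.data.shape[0] - 1, 1)] = 1.0  # foreground class
    else:
        seed[:] = 1.0
    out.backward(seed)
    act = acts[target_layer]
    if act.grad is None:
        heat = np.zeros(act.data.shape[1:])
    else:
        spatial_axes = tuple(range(1, act.data.ndim))
        weights = act.grad.mean(axis=spatial_axes)
        heat = np.maximum(np.tensordot(weights, act.data, axes=([0], [0])), 0.0)
    target = x.shape[1:]
    if heat.shape != target:
        heat = ad.upsample_linear(Tensor(heat[None]), target).data[0]
        heat = np.maximum(heat, 0.0)
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return heat


# -- checkpointing ---------------------------------------------------------

_BUILDERS = {"UNet": build_unet, "VNet": build_vnet, "SegChaNet": build_segchanet}


def save_checkpoint(net: SegmentationNetwork, path, extra: dict | None = None) -> Path:
    """Write parameters + NetworkConfig (npz + embedded JSON), versioned."""
    path = Path(path)
    meta = {"format_version": 1, "architecture": type(net).__name__,
            "config": _jsonable(asdict(net.config)), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path) -> tuple[SegmentationNetwork, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("dilation_schedule", "cam_levels"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    cfg = NetworkConfig(**cfg_dict)
    net = _BUILDERS[meta["architecture"]](cfg, seed=0)
    net.load_state_dict(state)
    return net, meta


def _jsonable(d: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
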