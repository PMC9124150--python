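"""Model/Results facade over the segmentation stack.

:class:`SegmentationModel` is constructed from data plus configuration and
``fit()`` returns a :class:`SegmentationResults` carrying the trained
network, the training history, and evaluation/prediction/summary methods —
the familiar fit-then-inspect workflow of statistical modelling packages,
wrapped around the lower-level :mod:`camseg.training` API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from . import training as T
from .losses import soft_dice_score
from .networks import (NetworkConfig, SegmentationNetwork, build_segchanet,
                       build_unet, build_vnet, forward, predict_mask)

_ARCHITECTURES = {"unet": build_unet, "vnet": build_vnet, "segchanet": build_segchanet}


@dataclass
class SegmentationModel:
    """A segmentation network specification bound to a training dataset.

    ``train_cases`` / ``val_cases`` are sequences of (volume, mask) pairs
    (arrays, CTVolume/LabelMask, or PhantomCase).
    """

    train_cases: list
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: T.TrainConfig = field(default_factory=T.TrainConfig)
    val_cases: list | None = None
    architecture: str = "segchanet"

    def build(self) -> SegmentationNetwork:
        try:
            builder = _ARCHITECTURES[self.architecture]
        except KeyError:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {sorted(_ARCHITECTURES)}") from None
        return builder(self.network, seed=self.train.seed)

    def fit(self, augment_fn=None) -> "SegmentationResults":
        net = self.build()
        net, history = T.train_model(net, self.train_cases, self.train,
                                     val_dataset=self.val_cases, augment_fn=augment_fn)
        return SegmentationResults(model=self, net=net, history=history)


@dataclass
class SegmentationResults:
    model: SegmentationModel
    net: SegmentationNetwork
    history: T.TrainHistory

    def predict(self, vol, threshold: float = 0.5):
        """Probability map and thresholded mask for one volume."""
        prob = forward(self.net, vol)
        return prob, predict_mask(prob, threshold)

    def evaluate(self, cases, tolerance_mm: float = 4.0) -> pd.DataFrame:
        """Per-case metric report over held-out cases."""
        rows = []
        for i, case in enumerate(cases):
            x, y = T._as_xy(case)
            prob = forward(self.net, x)
            pred = predict_mask(prob)
            report = M.evaluate_case(pred.data, y.astype(np.int16),
                                     tolerance_mm=tolerance_mm, on_empty="nan")
            row = {"case": i, **report.as_dict(),
                   "soft_dsc": soft_dice_score(y, prob.squeeze(0)
                                               if prob.shape[0] == 1 else prob)}
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary (printed table)."""
        cfg, tcfg = self.model.network, self.model.train
        final = self.history.final
        lines = [
            "Segmentation model fit",
            "=" * 54,
            f"architecture:     {type(self.net).__name__}",
            f"depth / base ch.: {cfg.depth} / {cfg.base_channels}"
            f"   channel attention: {'on' if cfg.use_cam else 'off'}",
            f"parameters:       {self.net.parameter_count():,}",
            f"loss:             {tcfg.loss}   optimizer: Adam(lr={tcfg.initial_lr:g})",
            f"epochs run:       {len(self.history.records)}",
            f"final train loss: {final.get('train_loss', float('nan')):.4f}",
        ]
        if final.get("val_loss") is not None:
            lines.append(f"final val BCE:    {final['val_loss']:.4f}")
        lines.append(f"final lr:         {final.get('lr', tcfg.initial_lr):g}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def save(self, path):
        return T.save_checkpoint(self.net, path,
                                 extra={"history": self.history.records})
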