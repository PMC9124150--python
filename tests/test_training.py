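"""Training protocol: schedule semantics, determinism, ensembling,
hyperparameter grid and grad-CAM."""

import numpy as np
import pytest

from camseg.networks import NetworkConfig, build_segchanet
from camseg.nn import autodiff as ad
from camseg.nn.autodiff import Tensor
from camseg.nn.layers import Conv, Module
from camseg.training import (TrainConfig, TrainHistory, ensemble_majority_vote,
                             gradcam_heatmap, kfold_split, load_checkpoint,
                             reduce_lr_on_plateau, run_hyperparameter_grid,
                             save_checkpoint, train_model)
from camseg.types import LabelMask

RNG = np.random.default_rng(6)


def tiny_cfg(**kw):
    base = dict(spatial_dims=2, depth=2, base_channels=3, dilation_schedule=(1,),
                use_cam=True)
    base.update(kw)
    return NetworkConfig(**base)


def tiny_cases(n=2, seed=0, size=16):
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        y = np.zeros((size, size))
        c = rng.integers(4, size - 4, size=2)
        yy, xx = np.mgrid[:size, :size]
        y[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= 9] = 1
        x = y * 2.0 - 1.0 + rng.normal(0, 0.2, size=y.shape)
        cases.append((x.astype(np.float32), y))
    return cases


def _history(values, lr=5e-4):
    h = TrainHistory()
    for i, v in enumerate(values):
        h.append(epoch=i, train_loss=v, val_loss=v, lr=lr)
    return h


def test_plateau_schedule_published_constants():
    """From 5e-4: 15 stagnant epochs give one x0.1 cut, 30 give two."""
    cfg = TrainConfig(initial_lr=5e-4, lr_patience=15, lr_factor=0.1)
    flat15 = _history([1.0] + [2.0] * 15)
    np.testing.assert_allclose(reduce_lr_on_plateau(flat15, cfg), 5e-5)
    improving = _history([1.0] + [2.0] * 13 + [0.5])
    np.testing.assert_allclose(reduce_lr_on_plateau(improving, cfg), 5e-4)
    flat30 = _history([1.0] + [2.0] * 30)
    np.testing.assert_allclose(reduce_lr_on_plateau(flat30, cfg), 5e-6)


def test_history_rejects_lr_increase():
    h = _history([1.0, 0.9])
    with pytest.raises(ValueError):
        h.append(epoch=2, train_loss=0.8, val_loss=0.8, lr=1e-3)


def test_zero_epochs_leaves_parameters_unchanged():
    net = build_segchanet(tiny_cfg(), seed=7)
    before = [p.data.copy() for p in net.parameters()]
    train_model(net, tiny_cases(), TrainConfig(epochs=0))
    for a, b in zip(before, net.parameters()):
        np.testing.assert_array_equal(a, b.data)


def test_training_is_deterministic_given_seed():
    runs = []
    for _ in range(2):
        net = build_segchanet(tiny_cfg(), seed=7)
        _, hist = train_model(net, tiny_cases(), TrainConfig(
            epochs=3, minibatch=2, initial_lr=1e-3, seed=11))
        runs.append(hist.to_frame())
    assert runs[0].equals(runs[1])


def test_training_reduces_loss_and_monitors_validation():
    net = build_segchanet(tiny_cfg(), seed=8)
    cases = tiny_cases(3, seed=1)
    _, hist = train_model(net, cases[:2], TrainConfig(epochs=15, minibatch=2,
                                                      initial_lr=3e-3, seed=0),
                          val_dataset=cases[2:])
    frame = hist.to_frame()
    assert frame.train_loss.iloc[-1] < frame.train_loss.iloc[0]
    assert frame.val_loss.notna().all()
    lrs = frame.lr.to_numpy()
    assert (np.diff(lrs) <= 1e-15).all()


def test_empty_and_inconsistent_datasets_rejected():
    net = build_segchanet(tiny_cfg(), seed=0)
    with pytest.raises(ValueError):
        train_model(net, [], TrainConfig())
    bad = [(np.zeros((16, 16), dtype=np.float32), np.zeros((16, 16))),
           (np.zeros((32, 32), dtype=np.float32), np.zeros((32, 32)))]
    with pytest.raises(Exception):
        train_model(net, bad, TrainConfig(epochs=1))


def test_hyperparameter_grid_shape_and_determinism():
    cases = tiny_cases(2, seed=2)
    grid = [(1e-3, 2), (1e-3, 2), (3e-3, 1)]
    table = run_hyperparameter_grid(cases, grid, tiny_cfg(),
                                    TrainConfig(epochs=2, seed=5))
    assert len(table) == 3
    assert table.loc[0, "val_dsc"] == table.loc[1, "val_dsc"]  # identical rows
    assert table.attrs["best_run"] in (1, 2, 3)
    with pytest.raises(ValueError):
        run_hyperparameter_grid(cases, [], tiny_cfg(), TrainConfig())


def test_majority_vote_worked_example_and_properties():
    base = np.zeros((2, 2, 2), dtype=np.int16)
    votes = [base.copy() for _ in range(5)]
    for m in votes[:3]:
        m[0, 0, 0] = 1  # per-voxel votes (1,1,1,0,0)
    out = ensemble_majority_vote(votes)
    assert out.data[0, 0, 0] == 1 and out.data.sum() == 1
    member = LabelMask((RNG.random((4, 4, 4)) > 0.5).astype(np.int16))
    same = ensemble_majority_vote([member] * 5)
    np.testing.assert_array_equal(same.data, member.data)
    # flipping any 2 of 5 members never overturns a unanimous vote
    flipped = [member.with_data(1 - member.data)] * 2 + [member] * 3
    np.testing.assert_array_equal(ensemble_majority_vote(flipped).data, member.data)
    with pytest.raises(ValueError):
        ensemble_majority_vote([member] * 4)


def test_majority_vote_matches_counting_oracle():
    rng = np.random.default_rng(21)
    members = [(rng.random((3, 3, 3)) > 0.5).astype(np.int16) for _ in range(5)]
    out = ensemble_majority_vote(members)
    for idx in np.ndindex(3, 3, 3):
        count = sum(m[idx] for m in members)
        assert out.data[idx] == (1 if count >= 3 else 0)


def test_kfold_partitions_every_case_once():
    folds = kfold_split(13, 5, seed=3)
    seen = np.concatenate(folds)
    assert sorted(seen.tolist()) == list(range(13))
    again = kfold_split(13, 5, seed=3)
    for a, b in zip(folds, again):
        np.testing.assert_array_equal(a, b)


class _ToyNet(Module):
    """One 1x1 conv + sigmoid over a 2-voxel 1D-like grid (2D, 1x2)."""

    def __init__(self, w):
        rng = np.random.default_rng(0)
        self.conv = Conv(1, 1, 1, 2, rng)
        self.conv.weight.data[:] = w
        self.conv.bias.data[:] = 0
        self.config = NetworkConfig(spatial_dims=2, depth=2, base_channels=1,
                                    dilation_schedule=(1,))

    def forward(self, x, training=False, record=False):
        h = self.conv(x)
        self._activations = {"act": h}
        return ad.sigmoid(h)

    @property
    def activations(self):
        return self._activations


def test_gradcam_toy_closed_form():
    """For act = w*x and score = sum(sigmoid(act)), the channel weight is
    mean(sigmoid'(act)) and the heatmap is relu(weight * act), normalised."""
    w = 1.5
    net = _ToyNet(w)
    x = np.array([[[0.5, -2.0]]], dtype=np.float64)
    heat = gradcam_heatmap(net, x, "act")
    act = w * x[0]
    s = 1 / (1 + np.exp(-act))
    weight = (s * (1 - s)).mean()
    expected = np.maximum(weight * act, 0)
    if expected.max() > 0:
        expected = expected / expected.max()
    np.testing.assert_allclose(heat, expected, atol=1e-10)


def test_gradcam_contracts_on_real_network():
    net = build_segchanet(tiny_cfg(), seed=9)
    x = RNG.normal(size=(16, 16)).astype(np.float32)
    heat = gradcam_heatmap(net, x, "enc0")
    assert heat.shape == (16, 16)
    assert heat.min() >= 0.0 and heat.max() <= 1.0 + 1e-9
    with pytest.raises(KeyError):
        gradcam_heatmap(net, x, "nonexistent")


def test_gradcam_zero_network_gives_zero_heatmap():
    net = build_segchanet(tiny_cfg(), seed=10)
    for p in net.parameters():
        p.data[:] = 0
    x = RNG.normal(size=(16, 16)).astype(np.float32)
    heat = gradcam_heatmap(net, x, "enc0")
    np.testing.assert_array_equal(heat, 0.0)


def test_checkpoint_roundtrip_preserves_predictions(tmp_path):
    net = build_segchanet(tiny_cfg(), seed=12)
    x = RNG.normal(size=(1, 16, 16)).astype(np.float32)
    before = net.forward(Tensor(x)).data
    path = save_checkpoint(net, tmp_path / "ckpt.npz", extra={"note": "test"})
    restored, meta = load_checkpoint(path)
    assert meta["extra"]["note"] == "test"
    after = restored.forward(Tensor(x)).data
    np.testing.assert_allclose(after, before, atol=1e-7)
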