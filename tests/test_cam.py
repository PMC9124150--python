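"""Channel-attention fusion against a straight-line index-level oracle."""

import numpy as np
import pytest

from camseg.cam import (CAMBlock, CAMParams, FeatureMap, cam_fuse, channel_gate,
                        global_avg_pool, low_level_transform, upsample_to)
from camseg.errors import ShapeError
from camseg.nn.autodiff import Tensor, _linear_interp_matrix

RNG = np.random.default_rng(2)


# --- independent oracle: literal per-index evaluation of the fusion -------

def oracle_cam(x_l, x_h, params):
    """Straight-line CAM: explicit loops for conv3, pooling, gating, and a
    separable linear upsample, mirroring the per-pixel definition."""
    c_h, c_l = params.conv3_weights.shape[:2]
    nd = x_l.ndim - 1
    k = params.conv3_weights.shape[2:]
    # conv3, same padding, literal sliding window
    pad = [(0, 0)] + [(ki // 2, ki // 2) for ki in k]
    xp = np.pad(x_l, pad)
    x_lp = np.zeros((c_h,) + x_l.shape[1:])
    for co in range(c_h):
        for pos in np.ndindex(*x_l.shape[1:]):
            acc = params.conv3_bias[co]
            for ci in range(c_l):
                for tap in np.ndindex(*k):
                    src = tuple(p + t for p, t in zip(pos, tap))
                    acc += params.conv3_weights[(co, ci) + tap] * xp[(ci,) + src]
            x_lp[(co,) + pos] = acc
    # conv1 (pointwise)
    conv1 = np.tensordot(params.conv1_weights.reshape(c_h, c_h), x_lp, axes=([1], [0]))
    conv1 += params.conv1_bias.reshape((c_h,) + (1,) * nd)
    # gate: global mean of each high-level channel
    g = x_h.reshape(x_h.shape[0], -1).mean(axis=1)
    x_gl = conv1 * g.reshape((-1,) + (1,) * nd)
    # separable linear upsample of x_h to x_l's grid
    up = x_h
    for ax in range(nd):
        m = _linear_interp_matrix(up.shape[1 + ax], x_l.shape[1 + ax])
        up = np.moveaxis(np.tensordot(m, up, axes=([1], [1 + ax])), 0, 1 + ax)
    return x_gl + up


def random_params(c_l, c_h, nd, seed=0):
    rng = np.random.default_rng(seed)
    return CAMParams(rng.normal(size=(c_h, c_l) + (3,) * nd), rng.normal(size=c_h),
                     rng.normal(size=(c_h, c_h) + (1,) * nd), rng.normal(size=c_h))


def test_global_avg_pool_examples_and_oracle():
    ones = FeatureMap(np.ones((1, 4, 4)))
    np.testing.assert_allclose(global_avg_pool(ones), [1.0])
    quad = FeatureMap(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
    np.testing.assert_allclose(global_avg_pool(quad), [2.5])
    x = RNG.normal(size=(4, 8, 8))
    explicit = np.array([sum(x[k, i, j] for i in range(8) for j in range(8)) / 64
                         for k in range(4)])
    np.testing.assert_allclose(global_avg_pool(FeatureMap(x)), explicit, atol=1e-12)


def test_upsample_constant_monotone_identity():
    const = FeatureMap(np.full((1, 3, 3), 3.0))
    np.testing.assert_allclose(upsample_to(const, (6, 6)).values, 3.0)
    cols = FeatureMap(np.array([[[0.0, 1.0], [0.0, 1.0]]]))
    up = upsample_to(cols, (4, 4)).values[0]
    assert (np.diff(up, axis=1) >= -1e-12).all()
    x = FeatureMap(RNG.normal(size=(2, 5, 5)))
    np.testing.assert_allclose(upsample_to(x, (5, 5)).values, x.values)
    with pytest.raises(ShapeError):
        upsample_to(x, (4, 5))


def test_low_level_transform_identity_zero_and_oracle():
    x = FeatureMap(RNG.normal(size=(3, 6, 6)))
    ident = CAMParams.identity(3, 2)
    np.testing.assert_allclose(low_level_transform(x, ident).values, x.values,
                               atol=1e-12)
    zero = CAMParams(np.zeros((3, 3, 3, 3)), np.zeros(3),
                     np.zeros((3, 3, 1, 1)), np.zeros(3))
    np.testing.assert_allclose(low_level_transform(x, zero).values, 0.0)
    with pytest.raises(ShapeError):
        low_level_transform(FeatureMap(RNG.normal(size=(2, 6, 6))),
                            random_params(3, 3, 2))


def test_channel_gate_examples():
    x = FeatureMap(RNG.normal(size=(3, 5, 5)))
    ident = CAMParams.identity(3, 2)
    np.testing.assert_allclose(channel_gate(x, np.ones(3), ident).values, x.values,
                               atol=1e-12)
    np.testing.assert_allclose(channel_gate(x, np.zeros(3), ident).values, 0.0)
    with pytest.raises(ShapeError):
        channel_gate(x, np.ones(4), ident)


def test_cam_fuse_zero_high_level_gives_zero():
    """With x_h = 0 and zero biases the gate scalars and the upsampled term
    both vanish, so the fused map is identically zero."""
    params = random_params(2, 3, 2, seed=1)
    params.conv3_bias[:] = 0
    params.conv1_bias[:] = 0
    x_l = FeatureMap(RNG.normal(size=(2, 8, 8)))
    x_h = FeatureMap(np.zeros((3, 4, 4)))
    np.testing.assert_allclose(cam_fuse(x_l, x_h, params).values, 0.0, atol=1e-12)


def test_cam_fuse_identity_kernels_constant_high_level():
    """Identity kernels and x_h constant at v: fusion reduces to v*x_l + v."""
    c, v = 3, 0.7
    params = CAMParams.identity(c, 2)
    x_l = FeatureMap(RNG.normal(size=(c, 6, 6)))
    x_h = FeatureMap(np.full((c, 3, 3), v))
    out = cam_fuse(x_l, x_h, params)
    np.testing.assert_allclose(out.values, v * x_l.values + v, atol=1e-12)


@pytest.mark.parametrize("spatial", [(8, 8), (8, 8, 8)])
def test_cam_fuse_matches_index_level_oracle(spatial):
    nd = len(spatial)
    half = tuple(s // 2 for s in spatial)
    x_l = RNG.normal(size=(4,) + spatial)
    x_h = RNG.normal(size=(4,) + half)
    params = random_params(4, 4, nd, seed=3)
    out = cam_fuse(FeatureMap(x_l), FeatureMap(x_h), params).values
    np.testing.assert_allclose(out, oracle_cam(x_l, x_h, params), atol=1e-6)


def test_cam_fuse_decomposition_isolates_gating():
    """X_cam - up(X_H) must equal the gated low-level component X_gL."""
    params = random_params(3, 3, 2, seed=4)
    x_l = FeatureMap(RNG.normal(size=(3, 8, 8)))
    x_h = FeatureMap(RNG.normal(size=(3, 4, 4)))
    fused = cam_fuse(x_l, x_h, params).values
    up = upsample_to(x_h, (8, 8)).values
    gl = channel_gate(low_level_transform(x_l, params), global_avg_pool(x_h),
                      params).values
    np.testing.assert_allclose(fused - up, gl, atol=1e-10)


def test_cam_dimension_agnostic():
    """2D and 3D paths agree on inputs constant along the extra axis."""
    params2 = random_params(2, 2, 2, seed=5)
    k3 = np.zeros((2, 2, 3, 3, 3))
    k3[:, :, 1] = params2.conv3_weights  # extrude: only the centre z-slab acts
    params3 = CAMParams(k3, params2.conv3_bias,
                        params2.conv1_weights[..., None], params2.conv1_bias)
    x_l2 = RNG.normal(size=(2, 6, 6))
    x_h2 = RNG.normal(size=(2, 3, 3))
    out2 = cam_fuse(FeatureMap(x_l2), FeatureMap(x_h2), params2).values
    reps = 5
    x_l3 = np.repeat(x_l2[:, None], reps, axis=1)
    x_h3 = np.repeat(x_h2[:, None], reps, axis=1)
    out3 = cam_fuse(FeatureMap(x_l3), FeatureMap(x_h3), params3).values
    # away from the z-borders the extruded 3D result equals the 2D one
    np.testing.assert_allclose(out3[:, reps // 2], out2, atol=1e-10)


def test_cam_block_matches_functional_form():
    """The trainable block and the functional composition share arithmetic."""
    block = CAMBlock(c_l=2, c_h=4, spatial_dims=3, rng=np.random.default_rng(6))
    x_l = RNG.normal(size=(2, 8, 8, 8)).astype(np.float64)
    x_h = RNG.normal(size=(4, 4, 4, 4)).astype(np.float64)
    block.conv3.weight.data = block.conv3.weight.data.astype(np.float64)
    block.conv1.weight.data = block.conv1.weight.data.astype(np.float64)
    block.conv3.bias.data = block.conv3.bias.data.astype(np.float64)
    block.conv1.bias.data = block.conv1.bias.data.astype(np.float64)
    got = block(Tensor(x_l), Tensor(x_h)).data
    want = cam_fuse(FeatureMap(x_l), FeatureMap(x_h), block.export_params()).values
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_cam_output_finite_on_finite_input():
    params = random_params(3, 5, 3, seed=8)
    x_l = FeatureMap(RNG.normal(size=(3, 8, 8, 8)) * 1e3)
    x_h = FeatureMap(RNG.normal(size=(5, 4, 4, 4)) * 1e3)
    assert np.all(np.isfinite(cam_fuse(x_l, x_h, params).values))
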