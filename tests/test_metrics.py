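"""Confusion-count metrics, Hausdorff and NSD against brute-force oracles."""

import numpy as np
import pytest

from camseg.errors import DegenerateInputError, ShapeError
from camseg.metrics import (ConfusionCounts, confusion_counts, evaluate_case,
                            hausdorff_distance, metrics_from_counts,
                            normalized_surface_distance, surface_voxels)

RNG = np.random.default_rng(4)


# --- brute-force oracles --------------------------------------------------

def loop_counts(pred, truth):
    tp = fp = tn = fn = 0
    for idx in np.ndindex(*pred.shape):
        p, t = pred[idx], truth[idx]
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def loop_surface(mask):
    out = np.zeros_like(mask, dtype=bool)
    for idx in np.ndindex(*mask.shape):
        if not mask[idx]:
            continue
        for ax in range(mask.ndim):
            for d in (-1, 1):
                n = list(idx)
                n[ax] += d
                if n[ax] < 0 or n[ax] >= mask.shape[ax] or not mask[tuple(n)]:
                    out[idx] = True
    return out


def allpairs_hausdorff(a, b, spacing):
    pa = np.argwhere(loop_surface(a)) * np.asarray(spacing)
    pb = np.argwhere(loop_surface(b)) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def allpairs_nsd(a, b, tol, spacing):
    pa = np.argwhere(loop_surface(a)) * np.asarray(spacing)
    pb = np.argwhere(loop_surface(b)) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    near_a = (d.min(axis=1) <= tol + 1e-9).sum()
    near_b = (d.min(axis=0) <= tol + 1e-9).sum()
    return (near_a + near_b) / (len(pa) + len(pb))


def random_mask(rng, p=0.3, shape=(6, 6, 6), nonempty=True):
    while True:
        m = (rng.random(shape) < p).astype(np.int16)
        if m.any() or not nonempty:
            return m


# --- tests ----------------------------------------------------------------

def test_confusion_counts_examples():
    truth = np.zeros((4, 4, 4), dtype=np.int16)
    truth[:2, :2, :2] = 1  # 8 foreground… use 10 of 64 via explicit voxels
    truth[3, 3, :2] = 1
    c = confusion_counts(truth, truth)
    assert (c.tp, c.fp, c.fn) == (10, 0, 0) and c.tn == 54
    comp = 1 - truth
    c2 = confusion_counts(comp, truth)
    assert c2.tp == 0 and c2.tn == 0 and c2.fp + c2.fn == 64


def test_confusion_counts_random_vs_loop_oracle():
    for seed in range(25):
        rng = np.random.default_rng(seed)
        p, t = random_mask(rng, nonempty=False), random_mask(rng, nonempty=False)
        c = confusion_counts(p, t)
        tp, fp, tn, fn = loop_counts(p, t)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.total == p.size


def test_metrics_from_counts_worked_example():
    rep = metrics_from_counts(ConfusionCounts(tp=3, fp=1, tn=59, fn=1))
    np.testing.assert_allclose(
        [rep.dsc, rep.sensitivity, rep.iou, rep.specificity],
        [0.75, 0.75, 0.6, 59 / 60], atol=1e-12)


def test_metrics_degenerate_conventions():
    rep = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=64, fn=0))
    assert rep.dsc == 1.0 and rep.iou == 1.0 and rep.sensitivity == 1.0
    rep2 = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=60, fn=4))
    assert rep2.dsc == 0.0 and rep2.iou == 0.0 and rep2.sensitivity == 0.0


def test_metrics_formula_oracle_random_counts():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, size=4))
        rep = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        np.testing.assert_allclose(rep.dsc, 2 * tp / (2 * tp + fp + fn), atol=1e-12)
        np.testing.assert_allclose(rep.sensitivity, tp / (tp + fn), atol=1e-12)
        np.testing.assert_allclose(rep.specificity, tn / (tn + fp), atol=1e-12)
        np.testing.assert_allclose(rep.iou, tp / (tp + fp + fn), atol=1e-12)
        np.testing.assert_allclose(rep.precision, tp / (tp + fp), atol=1e-12)


def test_dsc_iou_identity_random_pairs():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        c = confusion_counts(random_mask(rng), random_mask(rng))
        rep = metrics_from_counts(c)
        np.testing.assert_allclose(rep.dsc, 2 * rep.iou / (1 + rep.iou), atol=1e-12)


def test_overlap_symmetries():
    rng = np.random.default_rng(12)
    a, b = random_mask(rng), random_mask(rng)
    ra, rb = metrics_from_counts(confusion_counts(a, b)), \
        metrics_from_counts(confusion_counts(b, a))
    assert ra.dsc == rb.dsc and ra.iou == rb.iou
    assert ra.sensitivity == rb.precision and ra.precision == rb.sensitivity


def test_hausdorff_examples():
    m = np.zeros((5, 5, 5), dtype=np.int16)
    m[1:3, 1:3, 1:3] = 1
    assert hausdorff_distance(m, m) == 0.0
    a = np.zeros((6, 6, 6), dtype=np.int16)
    b = np.zeros((6, 6, 6), dtype=np.int16)
    a[0, 0, 0] = 1
    b[3, 4, 0] = 1
    np.testing.assert_allclose(hausdorff_distance(a, b), 5.0)
    with pytest.raises(DegenerateInputError):
        hausdorff_distance(a, np.zeros((6, 6, 6), dtype=np.int16))


def test_surface_extraction_matches_loop():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        m = random_mask(rng)
        np.testing.assert_array_equal(surface_voxels(m), loop_surface(m))


def test_hausdorff_and_nsd_match_allpairs_oracle():
    spacing = (1.5, 1.0, 2.0)
    for seed in range(15):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng), random_mask(rng)
        np.testing.assert_allclose(hausdorff_distance(a, b, spacing=spacing),
                                   allpairs_hausdorff(a, b, spacing), atol=1e-9)
        for tol in (0.0, 1.0, 2.5, 4.0):
            np.testing.assert_allclose(
                normalized_surface_distance(a, b, tol, spacing=spacing),
                allpairs_nsd(a, b, tol, spacing), atol=1e-9)


def test_hausdorff_triangle_inequality():
    spacing = (1.0, 1.0, 1.0)
    for seed in range(10):
        rng = np.random.default_rng(seed + 50)
        a, b, c = (random_mask(rng) for _ in range(3))
        dab = hausdorff_distance(a, b, spacing=spacing)
        dbc = hausdorff_distance(b, c, spacing=spacing)
        dac = hausdorff_distance(a, c, spacing=spacing)
        assert dac <= dab + dbc + 1e-9


def test_nsd_examples_and_monotonicity():
    m = np.zeros((5, 5, 5), dtype=np.int16)
    m[1:4, 1:4, 1:4] = 1
    assert normalized_surface_distance(m, m, 0.5) == 1.0
    a = np.zeros((12, 3, 3), dtype=np.int16)
    b = np.zeros((12, 3, 3), dtype=np.int16)
    a[0, 0, 0] = 1
    b[10, 0, 0] = 1  # 10 mm apart at unit spacing
    assert normalized_surface_distance(a, b, 4.0) == 0.0
    rng = np.random.default_rng(13)
    x, y = random_mask(rng), random_mask(rng)
    vals = [normalized_surface_distance(x, y, t) for t in (0, 1, 2, 3, 5, 10)]
    assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))


def test_evaluate_case_composition_and_degenerates():
    rng = np.random.default_rng(14)
    p, t = random_mask(rng), random_mask(rng)
    rep = evaluate_case(p, t, tolerance_mm=2.0)
    c = confusion_counts(p, t)
    manual = metrics_from_counts(c)
    assert rep.dsc == manual.dsc and rep.iou == manual.iou
    np.testing.assert_allclose(rep.hausdorff_mm, hausdorff_distance(p, t))
    np.testing.assert_allclose(rep.nsd, normalized_surface_distance(p, t, 2.0))
    perfect = evaluate_case(t, t, tolerance_mm=1.0)
    assert perfect.dsc == perfect.iou == perfect.sensitivity == perfect.nsd == 1.0
    assert perfect.hausdorff_mm == 0.0
    empty = evaluate_case(np.zeros_like(t), t)
    assert empty.dsc == 0.0 and empty.sensitivity == 0.0
    assert np.isnan(empty.hausdorff_mm)


def test_shape_and_label_validation():
    with pytest.raises(ShapeError):
        confusion_counts(np.zeros((3, 3, 3), dtype=int), np.zeros((4, 4, 4), dtype=int))
    with pytest.raises(ShapeError):
        confusion_counts(np.full((3, 3, 3), 2), np.zeros((3, 3, 3), dtype=int))
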