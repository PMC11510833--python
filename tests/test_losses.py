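"""IoU-family losses, Wise-IoU focusing behaviour and the detection loss."""

import numpy as np
import pytest

from yoloev.autograd import Tensor
from yoloev.boxes import Box, box_loss, iou, iou_matrix
from yoloev.losses import (DetectionLoss, TaskAlignedAssigner, WIoUState,
                           wiou_loss, wiou_loss_batch)
from yoloev.model import ModelConfig, build_model


# ------------------------------------------------------------- IoU family
def test_iou_closed_forms():
    assert iou(Box(0, 0, 1, 1), Box(0, 0, 1, 1)) == 1.0
    assert iou(Box(0, 0, 1, 1), Box(2, 0, 3, 1)) == 0.0
    assert np.isclose(iou(Box(0, 0, 2, 2), Box(1, 0, 3, 2)), 1 / 3)


def test_iou_symmetric_and_degenerate(rng):
    a, b = Box(0, 1, 4, 3), Box(1, 0, 2, 5)
    assert iou(a, b) == iou(b, a)
    with pytest.warns(UserWarning, match="degenerate"):
        assert iou(Box(0, 0, 0, 1), Box(0, 0, 1, 1)) == 0.0


@pytest.mark.parametrize("variant", ["iou", "giou", "diou", "ciou"])
def test_loss_zero_iff_identical(variant):
    assert box_loss(Box(1, 2, 4, 7), Box(1, 2, 4, 7), variant) == \
        pytest.approx(0.0, abs=1e-9)
    assert box_loss(Box(0, 0, 1, 1), Box(0.5, 0, 1.5, 1), variant) > 0


def test_giou_disjoint_closed_form():
    # IoU 0, union 2, enclosing box 3 -> loss = 1 - (0 - 1/3) = 4/3
    assert np.isclose(box_loss(Box(0, 0, 1, 1), Box(2, 0, 3, 1), "giou"), 4 / 3)
    assert 0 <= box_loss(Box(0, 0, 1, 1), Box(9, 9, 10, 10), "giou") <= 2


def test_diou_dominates_iou_loss(rng):
    """The centre-distance penalty is non-negative over random pairs."""
    for _ in range(1000):
        x1, y1, x2, y2 = rng.uniform(0, 8, 4)
        a = Box(min(x1, x2), min(y1, y2), max(x1, x2) + 0.1, max(y1, y2) + 0.1)
        dx, dy, s = rng.uniform(-3, 3), rng.uniform(-3, 3), rng.uniform(0.5, 2)
        b = Box(a.x1 + dx, a.y1 + dy, a.x1 + dx + s * (a.x2 - a.x1),
                a.y1 + dy + s * (a.y2 - a.y1))
        assert box_loss(a, b, "diou") >= box_loss(a, b, "iou") - 1e-12


@pytest.mark.parametrize("variant", ["iou", "giou", "diou", "ciou"])
def test_loss_invariant_under_joint_translation_and_scaling(variant, rng):
    a = Box(0.0, 1.0, 3.0, 4.0)
    b = Box(1.0, 0.5, 4.0, 5.0)
    ref = box_loss(a, b, variant)
    for _ in range(10):
        t, s = rng.uniform(-20, 20, 2), rng.uniform(0.1, 10)
        a2 = Box(s * (a.x1 + t[0]), s * (a.y1 + t[1]),
                 s * (a.x2 + t[0]), s * (a.y2 + t[1]))
        b2 = Box(s * (b.x1 + t[0]), s * (b.y1 + t[1]),
                 s * (b.x2 + t[0]), s * (b.y2 + t[1]))
        assert np.isclose(box_loss(a2, b2, variant), ref, atol=1e-9)


# ------------------------------------------------------------- Wise-IoU
def test_wiou_perfect_box_gives_zero_loss_and_gain():
    st = WIoUState(running_mean=0.5)
    loss, gain = wiou_loss(Box(0, 0, 2, 2), Box(0, 0, 2, 2), st)
    assert loss == 0.0 and gain == 0.0


def test_wiou_gain_is_one_at_beta_equals_delta():
    st = WIoUState(running_mean=1.0, alpha=1.9, delta=3.0)
    r = st.gain(np.array([3.0]))[0]  # beta = 3 = delta
    assert np.isclose(r, 1.0)


def test_wiou_frozen_closed_form_example():
    """pred (0,0,2,2) vs gt (1,0,3,2) at running mean 2/3:
    L_IoU = 2/3, R = exp(1/13), beta = 1, r = 1.9^2/3 -> loss 0.8664."""
    st = WIoUState(running_mean=2 / 3, alpha=1.9, delta=3.0)
    loss, gain = wiou_loss(Box(0, 0, 2, 2), Box(1, 0, 3, 2), st)
    assert np.isclose(gain, 1.2033, atol=1e-4)
    assert np.isclose(loss, 0.8664, atol=1e-4)


def test_wiou_gain_nonmonotonic_single_interior_maximum():
    st = WIoUState(running_mean=1.0)
    betas = np.linspace(1e-3, 20, 2000)
    r = st.gain(betas)
    assert (r >= 0).all()
    peak = r.argmax()
    assert 0 < peak < len(r) - 1
    assert (np.diff(r[:peak + 1]) > 0).all()       # rising to the peak
    assert (np.diff(r[peak:]) < 0).all()           # falling after it
    assert r[-1] < 0.1 * r[peak] and r[0] < 0.1 * r[peak]


def test_wiou_warmup_guard():
    st = WIoUState(running_mean=0.0)
    assert np.isclose(st.gain(np.array([0.7]))[0],
                      1.0 / (st.delta * st.alpha ** (1 - st.delta)))


def test_wiou_running_mean_updates_only_in_training():
    st = WIoUState(running_mean=0.5, momentum=0.1, updates=1)
    wiou_loss(Box(0, 0, 1, 1), Box(5, 5, 6, 6), st, training=False)
    assert st.running_mean == 0.5
    wiou_loss(Box(0, 0, 1, 1), Box(5, 5, 6, 6), st, training=True)
    assert np.isclose(st.running_mean, 0.9 * 0.5 + 0.1 * 1.0)


def test_wiou_batch_matches_scalar(rng):
    st1 = WIoUState(running_mean=0.4, updates=1)
    st2 = WIoUState(running_mean=0.4, updates=1)
    pairs = rng.uniform(0, 10, size=(16, 4))
    preds = np.stack([np.minimum(pairs[:, 0], pairs[:, 2]),
                      np.minimum(pairs[:, 1], pairs[:, 3]),
                      np.maximum(pairs[:, 0], pairs[:, 2]) + 0.5,
                      np.maximum(pairs[:, 1], pairs[:, 3]) + 0.5], axis=1)
    gts = preds[::-1] + rng.uniform(-1, 1, size=(16, 4)) * 0.3
    gts[:, 2:] = np.maximum(gts[:, 2:], gts[:, :2] + 0.1)
    batch, _ = wiou_loss_batch(Tensor(preds.astype(np.float32)), gts, st1,
                               training=False)
    for i in range(16):
        scalar, _ = wiou_loss(Box(*preds[i]), Box(*gts[i]), st2)
        assert np.isclose(batch.data[i], scalar, atol=1e-4)


def test_wiou_gradient_detachment_contract(rng):
    """Autograd gradients equal a finite-difference oracle that holds the
    gain, the outlier degree and the R denominator constant."""
    pred0 = np.array([[1.0, 1.0, 4.0, 3.0]], dtype=np.float32)
    gt = np.array([[2.0, 1.5, 5.0, 4.0]])
    st = WIoUState(running_mean=0.55, updates=1)

    p = Tensor(pred0.copy(), requires_grad=True)
    loss, gains = wiou_loss_batch(p, gt, st, training=False)
    loss.sum().backward()

    # oracle: loss = gain * exp(d^2 / C) * (1 - iou), C and gain frozen
    cw = max(pred0[0, 2], gt[0, 2]) - min(pred0[0, 0], gt[0, 0])
    ch = max(pred0[0, 3], gt[0, 3]) - min(pred0[0, 1], gt[0, 1])
    C = cw ** 2 + ch ** 2 + 1e-9
    g0 = gains[0]

    def frozen_loss(q):
        i = iou_matrix(q, gt)[0, 0]
        d2 = ((q[0, 0] + q[0, 2]) / 2 - (gt[0, 0] + gt[0, 2]) / 2) ** 2 + \
             ((q[0, 1] + q[0, 3]) / 2 - (gt[0, 1] + gt[0, 3]) / 2) ** 2
        return g0 * np.exp(d2 / C) * (1 - i)

    eps = 1e-4
    for j in range(4):
        q = pred0.astype(np.float64).copy()
        q[0, j] += eps
        fp = frozen_loss(q)
        q[0, j] -= 2 * eps
        fm = frozen_loss(q)
        assert np.isclose(p.grad[0, j], (fp - fm) / (2 * eps), atol=1e-2)


# --------------------------------------------------------------- assigner
def test_assigner_matches_obvious_anchor():
    assigner = TaskAlignedAssigner(topk=4)
    anchors = np.array([[8., 8.], [24., 8.], [8., 24.], [24., 24.]])
    scores = np.full((4, 2), 0.5)
    pboxes = np.stack([anchors[:, 0] - 6, anchors[:, 1] - 6,
                       anchors[:, 0] + 6, anchors[:, 1] + 6], axis=1)
    gt_boxes = np.array([[2., 2., 14., 14.]])   # around anchor 0
    fg, gidx, ts = assigner(scores, pboxes, anchors, np.array([1]), gt_boxes)
    assert fg[0] and not fg[1:].any()
    assert ts[0, 1] > 0 and ts[0, 0] == 0


def test_assigner_empty_ground_truth():
    assigner = TaskAlignedAssigner()
    fg, _, ts = assigner(np.full((5, 3), 0.5), np.zeros((5, 4)),
                         np.zeros((5, 2)), np.zeros(0), np.zeros((0, 4)))
    assert not fg.any() and ts.sum() == 0


# ----------------------------------------------------------- composite loss
@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig(scale="n", nc=3, imgsz=64, seed=0))


def test_detection_loss_zero_targets(tiny_model, rng):
    loss_fn = DetectionLoss(tiny_model)
    tiny_model.train()
    preds = tiny_model(Tensor(rng.normal(size=(1, 3, 64, 64))
                              .astype(np.float32) * 0.1))
    total, parts = loss_fn(preds, [(np.zeros(0), np.zeros((0, 4)))])
    assert parts["box"] == 0.0 and parts["dfl"] == 0.0
    assert parts["cls"] > 0 and np.isfinite(parts["total"])


def test_detection_loss_finite_and_positive(tiny_model, rng):
    loss_fn = DetectionLoss(tiny_model)
    tiny_model.train()
    preds = tiny_model(Tensor(rng.normal(size=(2, 3, 64, 64))
                              .astype(np.float32) * 0.1))
    targets = [(np.array([0]), np.array([[8., 8., 40., 40.]])),
               (np.array([1, 2]), np.array([[4., 4., 20., 28.],
                                            [30., 30., 60., 58.]]))]
    total, parts = loss_fn(preds, targets)
    assert all(np.isfinite(v) and v >= 0 for v in parts.values())
    assert parts["box"] > 0 and parts["dfl"] > 0


def test_saturated_classification_loss_is_small():
    """Near one-hot logits against the matching targets give a vanishing
    per-cell cross-entropy."""
    logits = Tensor(np.array([[12.0, -12.0, -12.0]], dtype=np.float32))
    target = np.array([[1.0, 0.0, 0.0]], dtype=np.float32)
    assert float(logits.bce_with_logits(target).sum().data) < 1e-3
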