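"""Training loops: backbone classifier and two-stage detector.

The detector step wires gradients through every component by hand: RoI-head
losses flow back through RoI align into the pyramid maps, RPN losses flow
back through the per-level heads into the same maps, and the summed map
gradients continue through the pyramid into the backbone.

Learning-rate schedules follow the step pattern of the reference setup:
the classifier starts at 0.01 and decays x0.1 every 10 epochs once past
epoch 50; the detector starts at 0.00125 with x0.1 drops after epochs 16
and 22 (momentum 0.9, weight decay 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .anchors import ClusterConfig, assign_anchors_to_levels, kmeans_iou
from .backbone import (
    DILATED,
    GROUPED,
    BackboneConfig,
    DCResNet,
    StageSpec,
)
from .detector import (
    DetectorConfig,
    TwoStageDetector,
    assign_proposal_levels,
    detections_to_array,
    generate_proposals,
    match_anchors_to_gt,
    sample_minibatch,
    to_chw_float,
)
from .losses import (
    LossParams,
    classification_loss,
    detection_loss,
    encode_box_deltas,
    regression_loss,
)
from .metrics import average_precision, mean_best_iou
from .pyramid import FeaturePyramid, PyramidConfig
from .synthetic import SceneConfig, generate_scene


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------

def backbone_lr(epoch: int, base: float = 0.01) -> float:
    """Base rate until epoch 50, then a tenth every further 10 epochs."""
    if epoch < 50:
        return base
    return base * 0.1 ** ((epoch - 50) // 10 + 1)


def detector_lr(epoch: int, base: float = 0.00125,
                drops: tuple[int, ...] = (16, 22)) -> float:
    """Two successive x0.1 drops after the listed epochs."""
    return base * 0.1 ** sum(epoch >= d for d in drops)


# --------------------------------------------------------------------------
# backbone classifier training
# --------------------------------------------------------------------------

def train_backbone_classifier(net: DCResNet, images, labels, *,
                              epochs: int = 5, batch_size: int = 32,
                              base_lr: float = 0.01, momentum: float = 0.9,
                              seed: int = 0, log=None):
    """SGD over uint8 HxWx3 crops with integer labels; returns history."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    opt = nn.SGD(net.parameters(), lr=base_lr, momentum=momentum)
    history = []
    n = len(images)
    for epoch in range(epochs):
        opt.lr = backbone_lr(epoch, base_lr)
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        net.train()
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = np.stack([to_chw_float(images[i]) for i in idx])
            x = net.normalize(batch)
            logits = net.forward_classify(x)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            net.zero_grad()
            net.backward_classify(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        entry = {"epoch": epoch, "lr": float(opt.lr),
                 "loss": float(epoch_loss / n), "accuracy": correct / n}
        history.append(entry)
        if log:
            log(entry)
    return history


# --------------------------------------------------------------------------
# detector training
# --------------------------------------------------------------------------

@dataclass
class StepLosses:
    rpn_cls: float
    rpn_reg: float
    head_cls: float
    head_reg: float
    total: float


def detector_train_step(det: TwoStageDetector, image, gt_boxes,
                        params: LossParams, opt: nn.SGD,
                        rng: np.random.Generator) -> StepLosses:
    """One SGD step on a single image with its ground-truth boxes."""
    cfg = det.config
    gt = np.asarray(gt_boxes, float).reshape(-1, 4)
    det.train()
    det.zero_grad()

    chw = to_chw_float(image)
    x = det.backbone.normalize(chw[None])
    feats = det.backbone.forward_features(x)
    pyr = det.pyramid.forward(feats)
    _, anchors, levels = det.level_anchors(pyr, feats.strides)

    # ---- stage 1: RPN ----
    logits, deltas = det.rpn_forward(pyr)
    labels, matched = match_anchors_to_gt(anchors, gt, cfg.rpn_pos_thr,
                                          cfg.rpn_neg_thr)
    pos, neg = sample_minibatch(labels, cfg.rpn_batch,
                                cfg.rpn_pos_fraction, rng)
    sel = np.concatenate([pos, neg]).astype(int)
    n_sampled = max(len(sel), 1)
    rpn_cls, dsel = classification_loss(logits[sel], labels[sel],
                                        n_cls=n_sampled)
    dlogits = np.zeros_like(logits)
    dlogits[sel] = dsel
    ddeltas = np.zeros_like(deltas)
    if len(pos):
        targets = encode_box_deltas(anchors[pos], gt[matched[pos]])
        rpn_reg, dpos = regression_loss(deltas[pos], targets,
                                        np.ones(len(pos), bool),
                                        n_sampled, params)
        ddeltas[pos] = params.lam * dpos
    else:
        rpn_reg = 0.0
    map_grads = det.rpn_backward(dlogits, ddeltas)

    # ---- proposals (no gradient flows through the boxes) ----
    obj = nn.softmax(logits, axis=1)[:, 1]
    h, w = image.shape[:2]
    proposals = generate_proposals(obj, deltas, anchors, levels, (w, h), cfg)
    prop_boxes = np.stack([p.box for p in proposals]) if proposals \
        else np.zeros((0, 4))
    if len(gt):  # standard trick: gt boxes join the proposal pool
        prop_boxes = np.vstack([prop_boxes, gt])

    head_cls = head_reg = 0.0
    if len(prop_boxes):
        p_labels, p_matched = match_anchors_to_gt(
            prop_boxes, gt, cfg.head_pos_thr, cfg.head_pos_thr)
        p_pos, p_neg = sample_minibatch(p_labels, cfg.head_batch,
                                        cfg.head_pos_fraction, rng)
        p_sel = np.concatenate([p_pos, p_neg]).astype(int)
        if len(p_sel):
            boxes_sel = prop_boxes[p_sel]
            box_levels = assign_proposal_levels(boxes_sel,
                                                det.level_anchor_areas)
            patches = det.roi_align.forward(pyr, feats.strides, boxes_sel,
                                            box_levels)
            scores, reg = det.roi_head.forward(patches)
            cls_targets = (p_labels[p_sel] == 1).astype(int)
            n2 = len(p_sel)
            head_cls, dscores = classification_loss(scores, cls_targets,
                                                    n_cls=n2)
            dreg = np.zeros_like(reg)
            pos_mask = cls_targets == 1
            if pos_mask.any():
                t = encode_box_deltas(boxes_sel[pos_mask],
                                      gt[p_matched[p_sel][pos_mask]])
                head_reg, dp = regression_loss(reg[pos_mask], t,
                                               np.ones(pos_mask.sum(), bool),
                                               n2, params)
                dreg[pos_mask] = params.lam * dp
            dpatches = det.roi_head.backward(dscores, dreg)
            for l, g in det.roi_align.backward(dpatches).items():
                if l in map_grads:
                    map_grads[l] = map_grads[l] + g
                else:
                    map_grads[l] = g

    dfeats = det.pyramid.backward(map_grads)
    det.backbone.backward_features(dfeats)
    opt.step()
    total = detection_loss(rpn_cls, rpn_reg, params) \
        + detection_loss(head_cls, head_reg, params)
    return StepLosses(rpn_cls=float(rpn_cls), rpn_reg=float(rpn_reg),
                      head_cls=float(head_cls), head_reg=float(head_reg),
                      total=float(total))


def clip_gradients(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class _ClippedSGD:
    """SGD wrapper applying global-norm gradient clipping before each step."""

    def __init__(self, opt: nn.SGD, max_norm: float):
        self._opt = opt
        self.max_norm = max_norm

    @property
    def lr(self):
        return self._opt.lr

    @lr.setter
    def lr(self, value):
        self._opt.lr = value

    def step(self):
        clip_gradients(self._opt.params, self.max_norm)
        self._opt.step()


def train_detector(det: TwoStageDetector, scenes, *, steps: int = 300,
                   params: LossParams | None = None, base_lr: float = 0.01,
                   momentum: float = 0.9, weight_decay: float = 1e-3,
                   warmup: int = 20, clip_norm: float = 10.0, seed: int = 0,
                   log=None):
    """SGD over (image, gt_boxes) pairs, cycling through ``scenes``.

    A short linear warmup precedes the base rate, and gradients are clipped
    to a global norm of ``clip_norm`` (single-image steps occasionally
    produce outlier gradients early on).  Returns per-step losses.
    """
    params = params or LossParams()
    rng = np.random.default_rng(seed)
    opt = nn.SGD(det.parameters(), lr=base_lr, momentum=momentum,
                 weight_decay=weight_decay)
    stepper = _ClippedSGD(opt, clip_norm) if clip_norm else opt
    order = rng.permutation(len(scenes))
    history = []
    for step in range(steps):
        if step % len(scenes) == 0 and step:
            order = rng.permutation(len(scenes))
        image, gt = scenes[order[step % len(scenes)]]
        stepper.lr = base_lr * min(1.0, (step + 1) / max(warmup, 1))
        losses = detector_train_step(det, image, gt, params, stepper, rng)
        history.append(losses)
        if log and (step % 25 == 0 or step == steps - 1):
            log(step, stepper.lr, losses)
    return history


# --------------------------------------------------------------------------
# evaluation helpers
# --------------------------------------------------------------------------

def evaluate_detector(det: TwoStageDetector, scenes,
                      iou_thrs=(0.5, 0.75)) -> dict[str, float]:
    """mAP at the requested thresholds plus mean best IoU on scenes
    given as (image, gt_boxes) pairs."""
    det_arrays, gt_arrays = [], []
    for image, gt in scenes:
        dets = det.detect(image)
        det_arrays.append(detections_to_array(dets))
        gt_arrays.append(np.asarray(gt, float).reshape(-1, 4))
    out = {}
    for thr in iou_thrs:
        out[f"mAP@{thr}"] = average_precision(det_arrays, gt_arrays, thr)
    out["mean_best_iou"] = mean_best_iou(det_arrays, gt_arrays)
    return out


def validation_objective(det: TwoStageDetector, scenes) -> float:
    """Kernel-free held-out objective for comparing training runs.

    Models trained under different regression kernels cannot be compared on
    either kernel's own loss (each is the quantity the other did not
    optimize), so this yardstick is kernel-free: the mean absolute RPN
    regression residual over all positive anchors plus the mean
    cross-entropy over all labelled anchors.  Lower is better for both
    terms; no weights are updated.
    """
    cfg = det.config
    abs_residual, n_coords = 0.0, 0
    ce_total, n_images = 0.0, 0
    det.eval()
    for image, gt_boxes in scenes:
        gt = np.asarray(gt_boxes, float).reshape(-1, 4)
        chw = to_chw_float(image)
        x = det.backbone.normalize(chw[None])
        feats = det.backbone.forward_features(x)
        pyr = det.pyramid.forward(feats)
        _, anchors, _ = det.level_anchors(pyr, feats.strides)
        logits, deltas = det.rpn_forward(pyr)
        labels, matched = match_anchors_to_gt(anchors, gt, cfg.rpn_pos_thr,
                                              cfg.rpn_neg_thr)
        pos = np.where(labels == 1)[0]
        if len(pos):
            t = encode_box_deltas(anchors[pos], gt[matched[pos]])
            abs_residual += float(np.abs(deltas[pos] - t).sum())
            n_coords += t.size
        sel = np.where(labels >= 0)[0]
        ce, _ = classification_loss(logits[sel], labels[sel])
        ce_total += ce
        n_images += 1
    return abs_residual / max(n_coords, 1) + ce_total / max(n_images, 1)


# --------------------------------------------------------------------------
# the miniature desk-scale benchmark
# --------------------------------------------------------------------------

MINI_SCENE = SceneConfig(width=128, height=128, n_cells=3,
                         abnormal_fraction=1.0,
                         cell_radius_range=(10.0, 24.0),
                         overlap_allowance=0.1, noise_sigma=4.0)


def mini_backbone_config() -> BackboneConfig:
    """A reduced stage plan for 128x128 scenes: strides 4 / 8 / 8."""
    return BackboneConfig(
        stem_channels=16,
        stages=(
            StageSpec(GROUPED, 1, (16, 16, 32), groups=4, stride=1),
            StageSpec(GROUPED, 1, (32, 32, 64), groups=4, stride=2),
            StageSpec(DILATED, 2, (64, 16, 64), dilation=2),
        ),
        head_dims=(64, 32, 2), input_size=128,
        input_mean=(0.85, 0.82, 0.87), input_std=(0.12, 0.12, 0.12))


def make_mini_scenes(n: int, seed: int, config: SceneConfig = MINI_SCENE):
    """(image, gt_boxes) pairs from the miniature scene regime."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img, ann, _ = generate_scene(config, seed=int(rng.integers(2**31)))
        out.append((img, ann.boxes))
    return out


def make_mini_detector(train_scenes, seed: int = 0, k: int = 6,
                       loss_params: LossParams | None = None):
    """Reduced detector whose anchors are clustered from ``train_scenes``."""
    boxes_wh = np.concatenate([
        np.stack([gt[:, 2] - gt[:, 0], gt[:, 3] - gt[:, 1]], axis=1)
        for _, gt in train_scenes if len(gt)])
    anchor_set = kmeans_iou(boxes_wh, ClusterConfig(k=k, seed=seed))
    backbone = DCResNet(mini_backbone_config(), seed=seed)
    pyr_cfg = PyramidConfig(selected_levels=(1, 2, 3), out_channels=32)
    levels = list(pyr_cfg.selected_levels)
    per_level = assign_anchors_to_levels(anchor_set, len(levels))
    pyramid = FeaturePyramid(
        {l: backbone.stages[l - 1][-1].out_channels for l in levels},
        pyr_cfg, rng=np.random.default_rng(seed + 1))
    det_cfg = DetectorConfig(rpn_batch=64, head_batch=32,
                             pre_nms_k=400, post_nms_k=50)
    det = TwoStageDetector(
        backbone, pyramid,
        {l: per_level[i] for i, l in enumerate(levels)},
        det_cfg, seed=seed + 2)
    det.loss_params = loss_params or LossParams()
    det.anchor_set = anchor_set
    return det
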