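"""Two-stage detection head: RPN pre-detection on the fused pyramid, RoI
feature extraction, and a classification + regression head.

The pipeline follows the classic two-stage recipe: dense anchors on every
pyramid level are scored and regressed by the RPN, the surviving proposals
are pooled into fixed-size patches (align-style bilinear sampling), and a
small fully connected head classifies each patch and refines its box.
Images are processed one at a time (batch dimension 1 internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .anchors import generate_anchor_grid, iou_boxes_matrix
from .losses import decode_box_deltas, encode_box_deltas


@dataclass
class Proposal:
    box: np.ndarray
    score: float
    level: int


@dataclass
class Detection:
    box: np.ndarray
    label: str
    score: float


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and sample sizes of the two stages."""

    rpn_pos_thr: float = 0.7
    rpn_neg_thr: float = 0.3
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    pre_nms_k: int = 1000
    post_nms_k: int = 100
    rpn_nms_thr: float = 0.7
    min_proposal_size: float = 1.0
    head_pos_thr: float = 0.5
    head_batch: int = 512
    head_pos_fraction: float = 0.25
    roi_size: int = 7
    score_thr: float = 0.05
    final_nms_thr: float = 0.5
    foreground_label: str = "abnormal"


# --------------------------------------------------------------------------
# matching and sampling
# --------------------------------------------------------------------------

def match_anchors_to_gt(anchors: np.ndarray, gt: np.ndarray,
                        pos_thr: float, neg_thr: float):
    """Labels (1 positive / 0 negative / -1 ignore) and matched gt index.

    An anchor is positive when its best IoU reaches ``pos_thr`` or when it
    is some gt box's best anchor (so every gt with any overlap owns at
    least one positive); negative when its best IoU is below ``neg_thr``.
    """
    if not 0.0 <= neg_thr <= pos_thr <= 1.0:
        raise ValueError(f"need 0 <= neg_thr <= pos_thr <= 1, got "
                         f"{neg_thr}, {pos_thr}")
    n = len(anchors)
    labels = np.full(n, -1, dtype=int)
    matched = np.full(n, -1, dtype=int)
    if len(gt) == 0:
        labels[:] = 0
        return labels, matched
    iou = iou_boxes_matrix(anchors, gt)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_gt]
    labels[best_iou < neg_thr] = 0
    pos = best_iou >= pos_thr
    labels[pos] = 1
    matched[pos] = best_gt[pos]
    # best-anchor rule: each gt claims its highest-IoU anchor(s)
    for j in range(gt.shape[0]):
        top = iou[:, j].max()
        if top <= 0:
            continue
        owners = np.where(iou[:, j] >= top - 1e-9)[0]
        labels[owners] = 1
        matched[owners] = j
    return labels, matched


def sample_minibatch(labels: np.ndarray, batch_size: int,
                     pos_fraction: float, rng: np.random.Generator):
    """Index arrays (pos_idx, neg_idx) honoring the positive fraction."""
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    n_pos = min(len(pos), int(round(batch_size * pos_fraction)))
    if len(pos) > n_pos:
        pos = rng.choice(pos, size=n_pos, replace=False)
    n_neg = min(len(neg), batch_size - len(pos))
    if len(neg) > n_neg:
        neg = rng.choice(neg, size=n_neg, replace=False)
    return pos, neg


# --------------------------------------------------------------------------
# proposal generation
# --------------------------------------------------------------------------

def clip_boxes(boxes: np.ndarray, width: float, height: float) -> np.ndarray:
    out = np.asarray(boxes, float).reshape(-1, 4).copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, width)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, height)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    boxes = np.asarray(boxes, float).reshape(-1, 4)
    order = np.argsort(-np.asarray(scores), kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        rest = order[1:]
        iou = iou_boxes_matrix(boxes[i][None], boxes[rest])[0]
        order = rest[iou < thr]
    return np.asarray(keep, dtype=int)


def generate_proposals(objectness: np.ndarray, deltas: np.ndarray,
                       anchors: np.ndarray, levels: np.ndarray,
                       image_size: tuple[int, int],
                       config: DetectorConfig) -> list[Proposal]:
    """Decode RPN outputs into scored, clipped, NMS-filtered proposals.

    ``objectness``: (n,) foreground probabilities; ``deltas``: (n, 4);
    ``levels``: (n,) source pyramid level per anchor;
    ``image_size``: (width, height).
    """
    boxes = decode_box_deltas(anchors, deltas)
    boxes = clip_boxes(boxes, *image_size)
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    valid = (w >= config.min_proposal_size) & (h >= config.min_proposal_size)
    boxes, scores, levels = boxes[valid], objectness[valid], levels[valid]
    if len(boxes) == 0:
        return []
    top = np.argsort(-scores, kind="stable")[:config.pre_nms_k]
    boxes, scores, levels = boxes[top], scores[top], levels[top]
    keep = nms(boxes, scores, config.rpn_nms_thr)[:config.post_nms_k]
    return [Proposal(box=boxes[i], score=float(scores[i]),
                     level=int(levels[i])) for i in keep]


def assign_proposal_levels(boxes: np.ndarray,
                           level_anchor_areas: dict[int, float]) -> np.ndarray:
    """Route each box to the pyramid level whose anchors are closest in
    log-area — the same small-to-shallow ordering the anchors use."""
    levels = sorted(level_anchor_areas)
    ref = np.log([level_anchor_areas[l] for l in levels])
    areas = np.log(np.maximum(
        (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]), 1e-6))
    idx = np.abs(areas[:, None] - ref[None, :]).argmin(axis=1)
    return np.asarray(levels, dtype=int)[idx]


# --------------------------------------------------------------------------
# RoI align
# --------------------------------------------------------------------------

class RoIAlign:
    """Align-style bilinear pooling to a fixed S x S patch (one sample per
    bin).  Caches sampling geometry so gradients can be scattered back."""

    def __init__(self, out_size: int = 7):
        self.out_size = out_size
        self._cache = None

    def forward(self, maps: dict[int, np.ndarray], strides: dict[int, int],
                boxes: np.ndarray, box_levels: np.ndarray) -> np.ndarray:
        s = self.out_size
        n = len(boxes)
        some_level = next(iter(maps))
        c = maps[some_level].shape[1]
        out = np.zeros((n, c, s, s), dtype=maps[some_level].dtype)
        cache = []
        for i, (box, level) in enumerate(zip(boxes, box_levels)):
            fmap = maps[int(level)][0]  # (C, H, W)
            stride = strides[int(level)]
            x0, y0, x1, y1 = box
            bw = max(x1 - x0, 1e-3) / s
            bh = max(y1 - y0, 1e-3) / s
            # bin-centre sample points in feature coordinates
            xs = (x0 + (np.arange(s) + 0.5) * bw) / stride - 0.5
            ys = (y0 + (np.arange(s) + 0.5) * bh) / stride - 0.5
            h, w = fmap.shape[1:]
            xs = np.clip(xs, 0, w - 1)
            ys = np.clip(ys, 0, h - 1)
            x_lo = np.floor(xs).astype(int)
            y_lo = np.floor(ys).astype(int)
            x_hi = np.minimum(x_lo + 1, w - 1)
            y_hi = np.minimum(y_lo + 1, h - 1)
            wx = xs - x_lo
            wy = ys - y_lo
            gy_lo, gx_lo = np.meshgrid(y_lo, x_lo, indexing="ij")
            gy_hi, gx_hi = np.meshgrid(y_hi, x_hi, indexing="ij")
            gwy, gwx = np.meshgrid(wy, wx, indexing="ij")
            p00 = fmap[:, gy_lo, gx_lo]
            p01 = fmap[:, gy_lo, gx_hi]
            p10 = fmap[:, gy_hi, gx_lo]
            p11 = fmap[:, gy_hi, gx_hi]
            out[i] = (p00 * (1 - gwy) * (1 - gwx) + p01 * (1 - gwy) * gwx
                      + p10 * gwy * (1 - gwx) + p11 * gwy * gwx)
            cache.append((int(level), gy_lo, gx_lo, gy_hi, gx_hi, gwy, gwx))
        self._cache = (cache, {l: m.shape for l, m in maps.items()})
        return out

    def backward(self, dout: np.ndarray) -> dict[int, np.ndarray]:
        """Per-level gradient maps matching the forward input shapes."""
        cache, shapes = self._cache
        grads = {l: np.zeros(shape, dtype=dout.dtype)
                 for l, shape in shapes.items()}
        for i, (level, gy_lo, gx_lo, gy_hi, gx_hi, gwy, gwx) in enumerate(cache):
            g = grads[level][0]
            d = dout[i]
            np.add.at(g, (slice(None), gy_lo, gx_lo), d * (1 - gwy) * (1 - gwx))
            np.add.at(g, (slice(None), gy_lo, gx_hi), d * (1 - gwy) * gwx)
            np.add.at(g, (slice(None), gy_hi, gx_lo), d * gwy * (1 - gwx))
            np.add.at(g, (slice(None), gy_hi, gx_hi), d * gwy * gwx)
        return grads


# --------------------------------------------------------------------------
# network heads
# --------------------------------------------------------------------------

class RPNHead(nn.Module):
    """Per-level RPN: shared 3x3 context conv, then 1x1 objectness (two
    logits per anchor) and 1x1 delta branches."""

    def __init__(self, in_channels: int, n_anchors: int, *,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.n_anchors = n_anchors
        self.conv = nn.Conv2d(in_channels, in_channels, 3, padding=1,
                              rng=rng, dtype=dtype)
        self.relu = nn.ReLU()
        self.cls = nn.Conv2d(in_channels, 2 * n_anchors, 1, rng=rng,
                             dtype=dtype)
        self.reg = nn.Conv2d(in_channels, 4 * n_anchors, 1, rng=rng,
                             dtype=dtype)

    def forward(self, fmap: np.ndarray):
        """(n_anchors*H*W, 2) objectness logits and (n_anchors*H*W, 4)
        deltas, ordered to match :func:`generate_anchor_grid`."""
        h = self.relu.forward(self.conv.forward(fmap))
        logits = self.cls.forward(h)
        deltas = self.reg.forward(h)
        n, _, hh, ww = logits.shape
        a = self.n_anchors
        # (1, A*K, H, W) -> (H*W*A, K): grid cell major, anchor minor
        logits = logits.reshape(a, 2, hh, ww).transpose(2, 3, 0, 1) \
            .reshape(-1, 2)
        deltas = deltas.reshape(a, 4, hh, ww).transpose(2, 3, 0, 1) \
            .reshape(-1, 4)
        self._shape = (a, hh, ww)
        return logits, deltas

    def backward(self, dlogits: np.ndarray, ddeltas: np.ndarray) -> np.ndarray:
        a, hh, ww = self._shape
        dl = dlogits.reshape(hh, ww, a, 2).transpose(2, 3, 0, 1) \
            .reshape(1, 2 * a, hh, ww)
        dd = ddeltas.reshape(hh, ww, a, 4).transpose(2, 3, 0, 1) \
            .reshape(1, 4 * a, hh, ww)
        dh = self.cls.backward(np.ascontiguousarray(dl)) \
            + self.reg.backward(np.ascontiguousarray(dd))
        return self.conv.backward(self.relu.backward(dh))


class RoIHead(nn.Module):
    """Two fc layers on flattened patches, then class scores (background /
    foreground) and a single-foreground-class box refinement."""

    def __init__(self, in_channels: int, roi_size: int, hidden: int = 256, *,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.flatten = nn.Flatten()
        self.fc1 = nn.Linear(in_channels * roi_size * roi_size, hidden,
                             rng=rng, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.fc2 = nn.Linear(hidden, hidden, rng=rng, dtype=dtype)
        self.relu2 = nn.ReLU()
        self.cls = nn.Linear(hidden, 2, rng=rng, dtype=dtype)
        self.reg = nn.Linear(hidden, 4, rng=rng, dtype=dtype)

    def forward(self, patches: np.ndarray):
        h = self.flatten.forward(patches)
        h = self.relu1.forward(self.fc1.forward(h))
        h = self.relu2.forward(self.fc2.forward(h))
        return self.cls.forward(h), self.reg.forward(h)

    def backward(self, dscores: np.ndarray, ddeltas: np.ndarray) -> np.ndarray:
        dh = self.cls.backward(dscores) + self.reg.backward(ddeltas)
        dh = self.relu2.backward(dh)
        dh = self.fc2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.fc1.backward(dh)
        return self.flatten.backward(dh)


# --------------------------------------------------------------------------
# postprocessing
# --------------------------------------------------------------------------

def postprocess_detections(proposals: list[Proposal], cls_scores: np.ndarray,
                           reg_deltas: np.ndarray,
                           image_size: tuple[int, int],
                           config: DetectorConfig) -> list[Detection]:
    """Softmax scores, refine boxes, threshold, per-class NMS, clip."""
    if not proposals:
        return []
    probs = nn.softmax(cls_scores, axis=1)
    fg = probs[:, 1]
    boxes = decode_box_deltas(np.stack([p.box for p in proposals]),
                              reg_deltas)
    boxes = clip_boxes(boxes, *image_size)
    keep = fg >= config.score_thr
    boxes, fg = boxes[keep], fg[keep]
    valid = (boxes[:, 2] > boxes[:, 0]) & (boxes[:, 3] > boxes[:, 1])
    boxes, fg = boxes[valid], fg[valid]
    if len(boxes) == 0:
        return []
    kept = nms(boxes, fg, config.final_nms_thr)
    return [Detection(box=boxes[i], label=config.foreground_label,
                      score=float(fg[i])) for i in kept]


def detections_to_array(detections: list[Detection]) -> np.ndarray:
    """(n, 5) [x0, y0, x1, y1, score] array for the metrics module."""
    if not detections:
        return np.zeros((0, 5))
    return np.asarray([[*d.box, d.score] for d in detections], float)


# --------------------------------------------------------------------------
# the two-stage detector
# --------------------------------------------------------------------------

class TwoStageDetector(nn.Module):
    """Backbone + pyramid + per-level RPN heads + RoI head.

    ``anchors_per_level``: {level: (k, 2) anchor shapes}; levels must be a
    subset of the pyramid's selected levels.
    """

    def __init__(self, backbone, pyramid, anchors_per_level: dict[int, np.ndarray],
                 config: DetectorConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.backbone = backbone
        self.pyramid = pyramid
        self.config = config or DetectorConfig()
        self.anchors_per_level = {
            int(l): np.asarray(a, float).reshape(-1, 2)
            for l, a in anchors_per_level.items()}
        rng = np.random.default_rng(seed)
        c = pyramid.config.out_channels
        self.rpn_heads = {
            l: RPNHead(c, len(a), rng=rng, dtype=dtype)
            for l, a in self.anchors_per_level.items()}
        self.roi_align = RoIAlign(self.config.roi_size)
        self.roi_head = RoIHead(c, self.config.roi_size, rng=rng, dtype=dtype)
        self.level_anchor_areas = {
            l: float(np.median(a[:, 0] * a[:, 1]))
            for l, a in self.anchors_per_level.items()}

    # -- shared plumbing -------------------------------------------------

    def extract_pyramid(self, image_chw: np.ndarray):
        feats = self.backbone.forward_features(image_chw[None])
        return feats, self.pyramid.forward(feats)

    def level_anchors(self, pyr: dict[int, np.ndarray],
                      strides: dict[int, int]):
        """Dense anchors per level plus flat concatenations."""
        per_level = {}
        for l, shapes in self.anchors_per_level.items():
            h, w = pyr[l].shape[2:]
            per_level[l] = generate_anchor_grid(h, w, strides[l], shapes)
        flat = np.concatenate([per_level[l] for l in sorted(per_level)])
        levels = np.concatenate([
            np.full(len(per_level[l]), l, dtype=int)
            for l in sorted(per_level)])
        return per_level, flat, levels

    def rpn_forward(self, pyr: dict[int, np.ndarray]):
        """Flat (n_anchors, 2) logits and (n_anchors, 4) deltas across
        levels, in the same order as :meth:`level_anchors`."""
        logits, deltas = [], []
        for l in sorted(self.anchors_per_level):
            lg, dl = self.rpn_heads[l].forward(pyr[l])
            logits.append(lg)
            deltas.append(dl)
        return np.concatenate(logits), np.concatenate(deltas)

    def rpn_backward(self, dlogits: np.ndarray, ddeltas: np.ndarray):
        """Split flat gradients per level; returns {level: dmap}."""
        grads = {}
        start = 0
        for l in sorted(self.anchors_per_level):
            a, hh, ww = self.rpn_heads[l]._shape
            n = a * hh * ww
            grads[l] = self.rpn_heads[l].backward(
                dlogits[start:start + n], ddeltas[start:start + n])
            start += n
        return grads

    # -- inference -------------------------------------------------------

    def detect(self, image: np.ndarray, rpn_override=None,
               head_override=None) -> list[Detection]:
        """Detections on one HxWx3 uint8 (or float) image.

        ``rpn_override(anchors, levels)`` and ``head_override(proposals)``
        replace the learned stages with externally supplied outputs — used
        by oracle tests that inject ground-truth-derived scores and deltas.
        """
        was_training = self.training
        self.eval()
        try:
            chw = to_chw_float(image)
            chw = self.backbone.normalize(chw[None])[0]
            feats, pyr = self.extract_pyramid(chw)
            _, anchors, levels = self.level_anchors(pyr, feats.strides)
            if rpn_override is not None:
                obj, deltas = rpn_override(anchors, levels)
            else:
                logits, deltas = self.rpn_forward(pyr)
                obj = nn.softmax(logits, axis=1)[:, 1]
            h, w = image.shape[:2]
            proposals = generate_proposals(obj, deltas, anchors, levels,
                                           (w, h), self.config)
            if not proposals:
                return []
            if head_override is not None:
                scores, reg = head_override(proposals)
            else:
                boxes = np.stack([p.box for p in proposals])
                box_levels = assign_proposal_levels(
                    boxes, self.level_anchor_areas)
                patches = self.roi_align.forward(pyr, feats.strides, boxes,
                                                 box_levels)
                scores, reg = self.roi_head.forward(patches)
            return postprocess_detections(proposals, scores, reg, (w, h),
                                          self.config)
        finally:
            self.train(was_training)


def to_chw_float(image: np.ndarray) -> np.ndarray:
    """HxWx3 uint8/float image -> (3, H, W) float32 in [0, 1]."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    return np.ascontiguousarray(img.transpose(2, 0, 1).astype(np.float32))


# --------------------------------------------------------------------------
# oracle injections (ground-truth-derived stage outputs)
# --------------------------------------------------------------------------

def oracle_rpn(gt_boxes: np.ndarray, match_thr: float = 0.05):
    """An RPN stand-in emitting certainty for each gt's best anchor.

    Every gt box claims its best-IoU anchor with objectness 1 and deltas
    that decode exactly onto the gt; all other anchors score 0.
    """
    gt = np.asarray(gt_boxes, float).reshape(-1, 4)

    def fn(anchors: np.ndarray, levels: np.ndarray):
        obj = np.zeros(len(anchors))
        deltas = np.zeros((len(anchors), 4))
        if len(gt):
            iou = iou_boxes_matrix(anchors, gt)
            for j in range(len(gt)):
                i = int(iou[:, j].argmax())
                if iou[i, j] >= match_thr:
                    obj[i] = 1.0
                    deltas[i] = encode_box_deltas(anchors[i][None],
                                                  gt[j][None])[0]
        return obj, deltas

    return fn


def oracle_head(gt_boxes: np.ndarray, match_thr: float = 0.5,
                logit_scale: float = 40.0):
    """A RoI-head stand-in scoring proposals by their true gt overlap."""
    gt = np.asarray(gt_boxes, float).reshape(-1, 4)

    def fn(proposals: list[Proposal]):
        boxes = np.stack([p.box for p in proposals])
        scores = np.zeros((len(boxes), 2))
        scores[:, 0] = logit_scale  # background by default
        deltas = np.zeros((len(boxes), 4))
        if len(gt):
            iou = iou_boxes_matrix(boxes, gt)
            best = iou.argmax(axis=1)
            best_iou = iou[np.arange(len(boxes)), best]
            for i in range(len(boxes)):
                if best_iou[i] >= match_thr:
                    scores[i, 0] = 0.0
                    scores[i, 1] = logit_scale * (0.5 + 0.5 * best_iou[i])
                    deltas[i] = encode_box_deltas(boxes[i][None],
                                                  gt[best[i]][None])[0]
        return scores, deltas

    return fn
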