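"""Two-stage detector: matching, NMS, proposals, RoI align, oracle paths."""

import numpy as np
import pytest

from cytodet import nn
from cytodet.anchors import iou_boxes_matrix
from cytodet.detector import (
    Detection,
    DetectorConfig,
    Proposal,
    RoIAlign,
    RPNHead,
    TwoStageDetector,
    assign_proposal_levels,
    clip_boxes,
    detections_to_array,
    generate_proposals,
    match_anchors_to_gt,
    nms,
    oracle_head,
    oracle_rpn,
    postprocess_detections,
    sample_minibatch,
)
from cytodet.metrics import average_precision
from cytodet.train import MINI_SCENE, make_mini_detector, make_mini_scenes


def greedy_nms_oracle(boxes, scores, thr):
    """Literal greedy suppression: repeatedly take the best-scored box and
    delete everything overlapping it at or above the threshold."""
    remaining = list(np.argsort(-np.asarray(scores), kind="stable"))
    kept = []
    while remaining:
        i = remaining.pop(0)
        kept.append(i)
        survivors = []
        for j in remaining:
            if iou_boxes_matrix(boxes[i][None], boxes[j][None])[0, 0] < thr:
                survivors.append(j)
        remaining = survivors
    return kept


class TestMatching:
    def test_identical_anchor_is_positive(self):
        gt = np.array([[10.0, 10.0, 30.0, 30.0]])
        labels, matched = match_anchors_to_gt(gt.copy(), gt, 0.7, 0.3)
        assert labels[0] == 1 and matched[0] == 0

    def test_disjoint_anchor_is_negative(self):
        anchors = np.array([[100.0, 100.0, 120.0, 120.0]])
        gt = np.array([[0.0, 0.0, 20.0, 20.0]])
        labels, _ = match_anchors_to_gt(anchors, gt, 0.7, 0.3)
        assert labels[0] == 0

    def test_no_gt_makes_everything_negative(self):
        anchors = np.array([[0.0, 0.0, 10.0, 10.0]])
        labels, matched = match_anchors_to_gt(anchors, np.zeros((0, 4)),
                                              0.7, 0.3)
        assert labels[0] == 0 and matched[0] == -1

    @pytest.mark.parametrize("seed", range(5))
    def test_every_overlapped_gt_owns_a_positive(self, seed):
        """Best-anchor rule: even when no anchor reaches pos_thr, each gt
        with any overlap gets at least one positive anchor.  Ground truths
        sit in separated neighbourhoods so their best anchors are distinct
        (two gts sharing one best anchor can only keep one claim)."""
        rng = np.random.default_rng(seed)
        anchors, gts = [], []
        for cx in (20.0, 120.0, 220.0):  # three well-separated clusters
            g0 = np.array([cx, 30.0]) + rng.uniform(-4, 4, 2)
            gts.append(np.concatenate([g0, g0 + rng.uniform(12, 18, 2)]))
            for _ in range(3):
                a0 = g0 + rng.uniform(-6, 6, 2)
                anchors.append(np.concatenate([a0, a0 + rng.uniform(8, 20, 2)]))
        anchors = np.asarray(anchors)
        gt = np.asarray(gts)
        labels, matched = match_anchors_to_gt(anchors, gt, 0.99, 0.3)
        iou = iou_boxes_matrix(anchors, gt)
        for j in range(len(gt)):
            if iou[:, j].max() > 0:
                owners = np.where((matched == j) & (labels == 1))[0]
                assert len(owners) >= 1
                assert iou[owners, j].max() == pytest.approx(iou[:, j].max())

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            match_anchors_to_gt(np.zeros((1, 4)), np.zeros((0, 4)), 0.3, 0.7)

    def test_minibatch_sampling_fractions(self):
        rng = np.random.default_rng(0)
        labels = np.array([1] * 10 + [0] * 100 + [-1] * 5)
        pos, neg = sample_minibatch(labels, 32, 0.5, rng)
        assert len(pos) == 10            # fewer positives than the quota
        assert len(neg) == 22            # negatives fill the batch
        assert np.all(labels[pos] == 1) and np.all(labels[neg] == 0)


class TestNMS:
    def test_duplicates_collapse(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert keep.tolist() == [0]

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        o = rng.uniform(0, 50, (20, 2))
        boxes = np.hstack([o, o + rng.uniform(5, 25, (20, 2))])
        scores = rng.random(20)
        keep1 = nms(boxes, scores, 0.5)
        keep2 = keep1[nms(boxes[keep1], scores[keep1], 0.5)]
        np.testing.assert_array_equal(keep1, keep2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        o = rng.uniform(0, 40, (5, 2))
        boxes = np.hstack([o, o + rng.uniform(5, 30, (5, 2))])
        scores = rng.random(5)
        assert nms(boxes, scores, 0.5).tolist() == \
            greedy_nms_oracle(boxes, scores, 0.5)


class TestProposals:
    def test_single_anchor_zero_deltas_returns_anchor(self):
        anchors = np.array([[10.0, 12.0, 30.0, 40.0]])
        props = generate_proposals(np.array([0.9]), np.zeros((1, 4)),
                                   anchors, np.array([1]), (100, 100),
                                   DetectorConfig())
        assert len(props) == 1
        np.testing.assert_allclose(props[0].box, anchors[0])
        assert props[0].level == 1

    def test_outputs_clipped_and_mutually_suppressed(self):
        rng = np.random.default_rng(2)
        o = rng.uniform(-30, 90, (60, 2))
        anchors = np.hstack([o, o + rng.uniform(10, 50, (60, 2))])
        cfg = DetectorConfig(rpn_nms_thr=0.6, post_nms_k=20)
        props = generate_proposals(rng.random(60), np.zeros((60, 4)),
                                   anchors, np.ones(60, int), (100, 100), cfg)
        boxes = np.stack([p.box for p in props])
        assert np.all(boxes >= 0) and np.all(boxes <= 100)
        if len(boxes) > 1:
            iou = iou_boxes_matrix(boxes, boxes)
            np.fill_diagonal(iou, 0)
            assert iou.max() < 0.6

    def test_clip_boxes(self):
        out = clip_boxes(np.array([[-5.0, -3.0, 120.0, 90.0]]), 100, 80)
        np.testing.assert_allclose(out, [[0, 0, 100, 80]])


class TestRoIAlign:
    def test_single_cell_proposal_replicates_cell_value(self):
        fmap = np.zeros((1, 1, 4, 4), np.float64)
        fmap[0, 0, 1, 2] = 7.0
        roi = RoIAlign(out_size=3)
        # stride 8: cell (row 1, col 2) covers image x in [16,24), y in [8,16)
        boxes = np.array([[16.0, 8.0, 24.0, 16.0]])
        patch = roi.forward({1: fmap}, {1: 8}, boxes, np.array([1]))
        assert patch.shape == (1, 1, 3, 3)
        np.testing.assert_allclose(patch[0, 0, 1, 1], 7.0)

    def test_identical_proposals_identical_patches(self):
        rng = np.random.default_rng(3)
        fmap = rng.standard_normal((1, 4, 8, 8))
        roi = RoIAlign(out_size=7)
        boxes = np.array([[5.0, 5.0, 40.0, 40.0]] * 2)
        patches = roi.forward({2: fmap}, {2: 8}, boxes, np.array([2, 2]))
        assert patches.shape == (2, 4, 7, 7)
        np.testing.assert_array_equal(patches[0], patches[1])

    def test_backward_is_exact_adjoint(self):
        rng = np.random.default_rng(4)
        fmap = rng.standard_normal((1, 3, 6, 6))
        roi = RoIAlign(out_size=5)
        boxes = np.array([[2.0, 3.0, 30.0, 28.0], [0.0, 0.0, 47.0, 47.0]])
        patches = roi.forward({1: fmap}, {1: 8}, boxes, np.array([1, 1]))
        dout = rng.standard_normal(patches.shape)
        grads = roi.backward(dout)
        lhs = float((patches * dout).sum())
        # linear op: <Ax, y> == <x, A^T y>
        rhs = float((fmap * grads[1]).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_level_routing_small_to_shallow(self):
        areas = {1: 16.0 * 16.0, 2: 40.0 * 40.0, 3: 90.0 * 90.0}
        boxes = np.array([[0, 0, 15, 15], [0, 0, 45, 38], [0, 0, 100, 80]],
                         float)
        np.testing.assert_array_equal(
            assign_proposal_levels(boxes, areas), [1, 2, 3])


class TestRPNHead:
    def test_output_counts_match_anchor_grid(self):
        rng = np.random.default_rng(5)
        head = RPNHead(8, n_anchors=3, rng=rng)
        fmap = rng.standard_normal((1, 8, 2, 2)).astype(np.float32)
        logits, deltas = head.forward(fmap)
        assert logits.shape == (12, 2) and deltas.shape == (12, 4)
        assert np.all(np.isfinite(logits)) and np.all(np.isfinite(deltas))
        l2, d2 = head.forward(fmap)
        np.testing.assert_array_equal(logits, l2)
        np.testing.assert_array_equal(deltas, d2)


class TestPostprocess:
    def test_all_background_yields_empty(self):
        props = [Proposal(np.array([0.0, 0.0, 10.0, 10.0]), 0.9, 1)]
        scores = np.array([[30.0, 0.0]])  # softmax ~ certain background
        out = postprocess_detections(props, scores, np.zeros((1, 4)),
                                     (64, 64), DetectorConfig())
        assert out == []

    def test_empty_proposals(self):
        assert postprocess_detections([], np.zeros((0, 2)),
                                      np.zeros((0, 4)), (64, 64),
                                      DetectorConfig()) == []

    def test_detections_to_array(self):
        dets = [Detection(np.array([1.0, 2.0, 3.0, 4.0]), "abnormal", 0.7)]
        arr = detections_to_array(dets)
        np.testing.assert_allclose(arr, [[1, 2, 3, 4, 0.7]])
        assert detections_to_array([]).shape == (0, 5)


@pytest.fixture(scope="module")
def mini():
    scenes = make_mini_scenes(6, seed=0)
    det = make_mini_detector(scenes, seed=0)
    return det, scenes


class TestOracleEndToEnd:
    def test_count_conservation_anchors_vs_rpn(self, mini):
        det, scenes = mini
        from cytodet.detector import to_chw_float

        chw = det.backbone.normalize(to_chw_float(scenes[0][0])[None])
        det.eval()
        feats = det.backbone.forward_features(chw)
        pyr = det.pyramid.forward(feats)
        _, anchors, _ = det.level_anchors(pyr, feats.strides)
        logits, deltas = det.rpn_forward(pyr)
        assert len(logits) == len(anchors) == len(deltas)

    def test_oracle_pipeline_reproduces_ground_truth(self, mini):
        """Injecting gt-derived scores/deltas at both stages returns the gt
        boxes exactly (IoU 1 each, mAP 1)."""
        det, scenes = mini
        image, gt = scenes[0]
        dets = det.detect(image, rpn_override=oracle_rpn(gt),
                          head_override=oracle_head(gt))
        assert len(dets) == len(gt)
        arr = detections_to_array(dets)
        iou = iou_boxes_matrix(arr[:, :4], gt)
        assert iou.max(axis=0).min() == pytest.approx(1.0, abs=1e-6)
        assert average_precision(arr, gt, 0.5) == pytest.approx(1.0)

    def test_untrained_detect_runs_and_stays_in_bounds(self, mini):
        det, scenes = mini
        dets = det.detect(scenes[1][0])
        for d in dets:
            assert 0 <= d.box[0] <= d.box[2] <= MINI_SCENE.width
            assert 0 <= d.box[1] <= d.box[3] <= MINI_SCENE.height
            assert 0.0 <= d.score <= 1.0
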