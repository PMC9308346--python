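"""Adaptive anchor shapes by K-means under the 1 - IoU distance.

Ground-truth box shapes are clustered as (width, height) pairs anchored at a
common origin, so the distance between a box and a cluster centre is
``1 - IoU`` of the two co-centred rectangles.  The resulting k shapes replace
hand-set anchor scales/ratios; they are sorted by area and dealt out
contiguously across pyramid levels, smallest shapes to the shallowest
(highest-resolution) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ClusteringError(ValueError):
    pass


# --------------------------------------------------------------------------
# IoU primitives
# --------------------------------------------------------------------------

def iou_centered(a, b) -> float:
    """IoU of two (w, h) shapes placed at a common origin."""
    wa, ha = float(a[0]), float(a[1])
    wb, hb = float(b[0]), float(b[1])
    if min(wa, ha, wb, hb) <= 0:
        raise ClusteringError(f"non-positive box dimensions: {a}, {b}")
    inter = min(wa, wb) * min(ha, hb)
    union = wa * ha + wb * hb - inter
    return inter / union


def iou_centered_matrix(boxes: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n, k) centred IoU between (n, 2) shapes and (k, 2) centres."""
    boxes = np.asarray(boxes, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if np.any(boxes <= 0) or np.any(centers <= 0):
        raise ClusteringError("non-positive box dimensions")
    inter = (np.minimum(boxes[:, None, 0], centers[None, :, 0])
             * np.minimum(boxes[:, None, 1], centers[None, :, 1]))
    union = (boxes[:, 0] * boxes[:, 1])[:, None] \
        + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return inter / union


def iou_boxes(a, b) -> float:
    """Standard corner-coordinate IoU; 0 for disjoint boxes."""
    return float(iou_boxes_matrix(np.asarray(a, float)[None],
                                  np.asarray(b, float)[None])[0, 0])


def iou_boxes_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, m) IoU between (n, 4) and (m, 4) [x0, y0, x1, y1] boxes."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    if np.any(a[:, 2] <= a[:, 0]) or np.any(a[:, 3] <= a[:, 1]) \
            or np.any(b[:, 2] <= b[:, 0]) or np.any(b[:, 3] <= b[:, 1]):
        raise ClusteringError("degenerate box (x_max <= x_min or y_max <= y_min)")
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterConfig:
    k: int = 15
    max_iterations: int = 300
    tol: float = 1e-8           # stop when the objective improves less
    seed: int = 0
    init: str = "kmeans++"      # or "random"; "kmeans++" diversifies restarts
    update: str = "mean"        # or "median"
    n_init: int = 10            # restarts; best objective kept
    refine: str = "auto"        # local-search refinement: auto | always | never
    refine_max_n: int = 64      # "auto" applies refinement up to this n


@dataclass
class AnchorSet:
    k: int
    shapes: np.ndarray                  # (k, 2), sorted by area ascending
    avg_iou: float
    objective: float                    # mean (1 - best-centre IoU)
    objective_history: list[float] = field(default_factory=list)
    per_level: list[np.ndarray] | None = None


def clustering_objective(boxes: np.ndarray, centers: np.ndarray) -> float:
    """Mean over boxes of (1 - IoU with the best centre)."""
    return float(1.0 - iou_centered_matrix(boxes, centers).max(axis=1).mean())


def _init_centers(boxes, k, rng, method):
    n = len(boxes)
    if method == "random":
        return boxes[rng.choice(n, size=k, replace=False)].copy()
    # k-means++ style seeding under the 1 - IoU distance
    centers = [boxes[rng.integers(n)]]
    for _ in range(1, k):
        d = 1.0 - iou_centered_matrix(boxes, np.array(centers)).max(axis=1)
        total = d.sum()
        if total <= 0:  # all boxes already coincide with a centre
            centers.append(boxes[rng.integers(n)])
            continue
        centers.append(boxes[rng.choice(n, p=d / total)])
    return np.array(centers)


def _partition_centers(boxes, assign, k, update):
    """Per-cluster mean (or median) shapes; every cluster must be non-empty."""
    centers = np.empty((k, 2))
    for j in range(k):
        members = boxes[assign == j]
        centers[j] = (np.median(members, axis=0) if update == "median"
                      else members.mean(axis=0))
    return centers


def _lloyd_run(boxes, k, rng, cfg: ClusterConfig, init_method):
    """One Lloyd run to an assignment fixed point, tracking the incumbent.

    The per-cluster mean of (w, h) is not the Frechet mean of the 1 - IoU
    metric, so a raw Lloyd step can (rarely, and slightly) worsen the
    objective.  The run therefore keeps the best partition-mean state seen
    so far (the incumbent); the recorded history is the incumbent objective
    after each iteration and is non-increasing by construction.
    """
    centers = _init_centers(boxes, k, rng, init_method)
    incumbent = None  # (objective, assignment)
    history = []
    prev_assign = None
    for _ in range(cfg.max_iterations):
        iou = iou_centered_matrix(boxes, centers)
        assign = iou.argmax(axis=1)  # ties -> lowest centre index
        # reseed empty clusters from the farthest box
        for j in range(k):
            if not np.any(assign == j):
                far = (1.0 - iou.max(axis=1)).argmax()
                centers[j] = boxes[far]
                iou = iou_centered_matrix(boxes, centers)
                assign = iou.argmax(axis=1)
        means = _partition_centers(boxes, assign, k, cfg.update)
        obj = clustering_objective(boxes, means)
        if incumbent is None or obj < incumbent[0]:
            incumbent = (obj, assign.copy())
        history.append(incumbent[0])
        converged = prev_assign is not None and np.array_equal(assign, prev_assign)
        stalled = len(history) >= 2 and history[-2] - history[-1] < cfg.tol
        if converged or stalled:
            break
        prev_assign = assign
        centers = means
    return incumbent, history


def _local_refine(boxes, assign, k, cfg: ClusterConfig, history):
    """Relocation + swap local search on the partition objective.

    Moves a single box to another cluster, or swaps two boxes between
    clusters, whenever that lowers the objective of the resulting
    mean-centre set; repeats sweeps until no move improves.  Escapes the
    Lloyd fixed points that are not local optima of the partition objective.
    Cost grows roughly as n^2 * k per sweep, so it is applied to small
    problems only under the default "auto" policy.
    """
    n = len(boxes)

    def objective():
        return clustering_objective(
            boxes, _partition_centers(boxes, assign, k, cfg.update))

    obj = objective()
    while True:
        improved = False
        for i in range(n):
            if np.sum(assign == assign[i]) == 1:
                continue  # moving would empty the cluster
            for j in range(k):
                if j == assign[i]:
                    continue
                old = assign[i]
                assign[i] = j
                cand = objective()
                if cand < obj - 1e-15:
                    obj, improved = cand, True
                else:
                    assign[i] = old
        for i in range(n):
            for i2 in range(i + 1, n):
                if assign[i] == assign[i2]:
                    continue
                assign[i], assign[i2] = assign[i2], assign[i]
                cand = objective()
                if cand < obj - 1e-15:
                    obj, improved = cand, True
                else:
                    assign[i], assign[i2] = assign[i2], assign[i]
        history.append(obj)
        if not improved:
            return obj, assign


def kmeans_iou(boxes, config: ClusterConfig | None = None) -> AnchorSet:
    """Cluster (w, h) boxes into k anchor shapes under the 1 - IoU distance.

    Restarted Lloyd iterations with k-means++ style seeding; the centroid
    update is the per-cluster arithmetic mean (or median) of (w, h).  On
    small inputs a relocation/swap local search refines the best run (see
    :func:`_local_refine`).  Deterministic for a fixed config; ``n_init``
    restarts keep the best objective.  ``objective_history`` records the
    incumbent objective per iteration of the winning restart and is
    non-increasing.
    """
    cfg = config or ClusterConfig()
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 2)
    if np.any(boxes <= 0):
        raise ClusteringError("non-positive box dimensions")
    distinct = np.unique(boxes, axis=0)
    if cfg.k < 1 or cfg.k > len(distinct):
        raise ClusteringError(
            f"k={cfg.k} must be in [1, number of distinct boxes={len(distinct)}]")
    rng = np.random.default_rng(cfg.seed)
    do_refine = cfg.refine == "always" or (
        cfg.refine == "auto" and len(boxes) <= cfg.refine_max_n)
    best = None  # (objective, assignment, history)
    for t in range(max(1, cfg.n_init)):
        if cfg.init == "random":
            init_method = "random"
        else:  # diversify restarts between ++-style and random seeding
            init_method = "kmeans++" if t % 2 == 0 else "random"
        (obj, assign), history = _lloyd_run(boxes, cfg.k, rng, cfg, init_method)
        if do_refine:
            obj, assign = _local_refine(boxes, assign, cfg.k, cfg, history)
        if best is None or obj < best[0]:
            best = (obj, assign, history)
    obj, assign, history = best
    centers = _partition_centers(boxes, assign, cfg.k, cfg.update)
    order = np.argsort(centers[:, 0] * centers[:, 1], kind="stable")
    shapes = centers[order]
    return AnchorSet(k=cfg.k, shapes=shapes,
                     avg_iou=avg_iou(boxes, shapes),
                     objective=obj, objective_history=history)


def avg_iou(boxes, anchors) -> float:
    """Mean over boxes of the best centred IoU against the anchor shapes."""
    shapes = anchors.shapes if isinstance(anchors, AnchorSet) else anchors
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 2)
    if len(boxes) == 0 or len(shapes) == 0:
        raise ClusteringError("avg_iou needs non-empty boxes and anchors")
    return float(iou_centered_matrix(boxes, np.asarray(shapes,
                                                       float)).max(axis=1).mean())


def assign_anchors_to_levels(anchors: AnchorSet | np.ndarray,
                             n_levels: int) -> list[np.ndarray]:
    """Deal shapes across levels: sort by area, contiguous split, smallest
    areas to the shallowest level.  When k is not divisible by n_levels the
    shallower levels receive the extra shapes."""
    shapes = anchors.shapes if isinstance(anchors, AnchorSet) else np.asarray(anchors, float)
    order = np.argsort(shapes[:, 0] * shapes[:, 1], kind="stable")
    parts = np.array_split(shapes[order], n_levels)
    if isinstance(anchors, AnchorSet):
        anchors.per_level = parts
    return parts


def generate_anchor_grid(map_height: int, map_width: int, stride: int,
                         shapes) -> np.ndarray:
    """Dense anchors: one box per (cell, shape), centred at (i+0.5)*stride.

    Returns an (H*W*n_shapes, 4) array in [x0, y0, x1, y1]; anchors may
    extend past the image and are clipped downstream.
    """
    shapes = np.asarray(shapes, dtype=float).reshape(-1, 2)
    if map_height < 1 or map_width < 1 or stride < 1:
        raise ValueError("map size and stride must be positive")
    cy = (np.arange(map_height) + 0.5) * stride
    cx = (np.arange(map_width) + 0.5) * stride
    gy, gx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (H*W, 2) as (x, y)
    half = shapes / 2.0
    boxes = np.concatenate([
        (centers[:, None, :] - half[None, :, :]),
        (centers[:, None, :] + half[None, :, :]),
    ], axis=2)
    return boxes.reshape(-1, 4)
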