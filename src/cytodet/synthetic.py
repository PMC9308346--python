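"""Synthetic cytology scenes with exact ground truth.

The generator emulates two liquid-based-cytology regimes:

* a *smear* regime — multi-cell fields (default 800x800) where squamous
  epithelial cells of widely varying size, aspect and orientation may
  overlap, rendered as stained cytoplasm ellipses with an inner nucleus;
* a *single-cell* regime — 200x100 crops containing one centred cell, for
  classifier experiments.

A cell's class is defined by its nucleus-to-cytoplasm area ratio: enlarged,
darkly stained nuclei are the morphological hallmark of abnormal squamous
cells, so ``abnormal`` means ratio above ``ratio_threshold``.  Because the
geometry is synthesized first and rendered second, bounding boxes and labels
are exact by construction, and the label can be re-derived from the rendered
masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

NORMAL, ABNORMAL = "normal", "abnormal"


class PackingError(RuntimeError):
    """Raised when cells cannot be placed under the overlap constraint."""


@dataclass(frozen=True)
class SceneConfig:
    """Generator settings for one scene regime.

    Sizes are pixels.  ``cell_radius_range`` bounds the cytoplasm
    semi-major axis; ``aspect_range`` the ratio of minor to major axis.
    ``overlap_allowance`` in [0, 1] scales how deeply two cytoplasm disks
    may interpenetrate (0 = disjoint, 1 = unconstrained).  Nucleus area
    ratios are drawn per class on either side of ``ratio_threshold``.
    """

    width: int = 800
    height: int = 800
    n_cells: int = 12
    abnormal_fraction: float = 0.5
    cell_radius_range: tuple[float, float] = (18.0, 70.0)
    aspect_range: tuple[float, float] = (0.55, 1.0)
    overlap_allowance: float = 0.3
    ratio_threshold: float = 0.2
    normal_ratio_range: tuple[float, float] = (0.05, 0.15)
    abnormal_ratio_range: tuple[float, float] = (0.3, 0.6)
    noise_sigma: float = 6.0
    max_place_attempts: int = 300


@dataclass(frozen=True)
class CellSpec:
    """Geometry and class of one rendered cell."""

    center: tuple[float, float]          # (x, y)
    cyto_axes: tuple[float, float]       # semi-axes (a, b), a >= b
    nucleus_axes: tuple[float, float]
    orientation: float                   # radians
    label: str
    cyto_color: tuple[int, int, int] = (170, 200, 225)
    nucleus_color: tuple[int, int, int] = (88, 60, 130)

    def __post_init__(self):
        if self.nucleus_axes[0] > self.cyto_axes[0] \
                or self.nucleus_axes[1] > self.cyto_axes[1]:
            raise ValueError("nucleus must be contained in the cytoplasm")
        if self.label not in (NORMAL, ABNORMAL):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def area_ratio(self) -> float:
        return (self.nucleus_axes[0] * self.nucleus_axes[1]) \
            / (self.cyto_axes[0] * self.cyto_axes[1])

    def bounding_box(self) -> np.ndarray:
        """Tight axis-aligned bound of the rotated cytoplasm ellipse."""
        a, b = self.cyto_axes
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        hw = math.sqrt((a * c) ** 2 + (b * s) ** 2)
        hh = math.sqrt((a * s) ** 2 + (b * c) ** 2)
        x, y = self.center
        return np.array([x - hw, y - hh, x + hw, y + hh])


@dataclass
class SceneAnnotation:
    image_id: str
    width: int
    height: int
    boxes: np.ndarray                    # (n, 4) float
    labels: list[str]
    seed: int
    config: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _ellipse_mask(h, w, center, axes, theta, box):
    """Boolean mask of a rotated ellipse, evaluated only inside ``box``."""
    x0, y0, x1, y1 = (max(0, int(math.floor(box[0]))),
                      max(0, int(math.floor(box[1]))),
                      min(w, int(math.ceil(box[2])) + 1),
                      min(h, int(math.ceil(box[3])) + 1))
    if x1 <= x0 or y1 <= y0:
        return (slice(0, 0), slice(0, 0)), np.zeros((0, 0), bool)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx + 0.5 - center[0]
    dy = yy + 0.5 - center[1]
    c, s = math.cos(theta), math.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mask = (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), mask


def render_cell_masks(cell: CellSpec, height: int, width: int):
    """Full-size boolean cytoplasm and nucleus masks of a single cell."""
    cyto = np.zeros((height, width), bool)
    nuc = np.zeros((height, width), bool)
    box = cell.bounding_box()
    sl, m = _ellipse_mask(height, width, cell.center, cell.cyto_axes,
                          cell.orientation, box)
    cyto[sl] = m
    sl, m = _ellipse_mask(height, width, cell.center, cell.nucleus_axes,
                          cell.orientation, box)
    nuc[sl] = m
    return cyto, nuc


def _render(cells: list[CellSpec], cfg: SceneConfig,
            rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    img = np.empty((h, w, 3), np.float64)
    img[...] = (236.0, 228.0, 238.0)  # pale smear background
    for cell in cells:
        box = cell.bounding_box()
        sl, m = _ellipse_mask(h, w, cell.center, cell.cyto_axes,
                              cell.orientation, box)
        # soft cytoplasm: semi-transparent so overlaps stay visible
        region = img[sl]
        color = np.asarray(cell.cyto_color, np.float64)
        region[m] = 0.35 * region[m] + 0.65 * color
        sl, m = _ellipse_mask(h, w, cell.center, cell.nucleus_axes,
                              cell.orientation, box)
        region = img[sl]
        color = np.asarray(cell.nucleus_color, np.float64)
        region[m] = 0.1 * region[m] + 0.9 * color
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# scene generation
# --------------------------------------------------------------------------

def _draw_cell(cfg: SceneConfig, label: str, rng) -> tuple:
    a = rng.uniform(*cfg.cell_radius_range)
    b = a * rng.uniform(*cfg.aspect_range)
    theta = rng.uniform(0.0, math.pi)
    lo, hi = (cfg.abnormal_ratio_range if label == ABNORMAL
              else cfg.normal_ratio_range)
    ratio = rng.uniform(lo, hi)
    scale = math.sqrt(ratio)
    nucleus = (a * scale, b * scale)
    if label == ABNORMAL:
        nuc_color = (60, 35, 95)   # hyperchromatic
        cyto_color = (180, 190, 215)
    else:
        nuc_color = (110, 85, 150)
        cyto_color = (165, 205, 225)
    return (a, b), nucleus, theta, cyto_color, nuc_color


def _class_plan(n_cells: int, abnormal_fraction: float) -> list[str]:
    n_abn = int(round(n_cells * abnormal_fraction))
    return [ABNORMAL] * n_abn + [NORMAL] * (n_cells - n_abn)


def generate_scene(config: SceneConfig | None = None, seed: int = 0,
                   image_id: str | None = None):
    """One multi-cell scene: returns (image HxWx3 uint8, annotation, cells).

    Deterministic under ``seed``.  Placement rejects candidates whose
    centre-to-centre distance violates the overlap allowance; an infeasible
    packing raises :class:`PackingError` after bounded attempts.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    labels = _class_plan(cfg.n_cells, cfg.abnormal_fraction)
    rng.shuffle(labels)

    cells: list[CellSpec] = []
    radii: list[float] = []
    for label in labels:
        axes, nucleus, theta, cyto_color, nuc_color = _draw_cell(cfg, label, rng)
        r = 0.5 * (axes[0] + axes[1])
        placed = False
        for _ in range(cfg.max_place_attempts):
            hw = math.sqrt((axes[0] * math.cos(theta)) ** 2
                           + (axes[1] * math.sin(theta)) ** 2)
            hh = math.sqrt((axes[0] * math.sin(theta)) ** 2
                           + (axes[1] * math.cos(theta)) ** 2)
            if 2 * hw >= cfg.width or 2 * hh >= cfg.height:
                axes = (axes[0] * 0.8, axes[1] * 0.8)
                nucleus = (nucleus[0] * 0.8, nucleus[1] * 0.8)
                continue
            x = rng.uniform(hw, cfg.width - hw)
            y = rng.uniform(hh, cfg.height - hh)
            ok = True
            for cell, r2 in zip(cells, radii):
                min_dist = (1.0 - cfg.overlap_allowance) * (r + r2)
                dx = x - cell.center[0]
                dy = y - cell.center[1]
                if dx * dx + dy * dy < min_dist * min_dist:
                    ok = False
                    break
            if ok:
                cells.append(CellSpec((x, y), axes, nucleus, theta, label,
                                      cyto_color, nuc_color))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place cell {len(cells) + 1}/{cfg.n_cells} within "
                f"{cfg.max_place_attempts} attempts (overlap allowance "
                f"{cfg.overlap_allowance})")

    image = _render(cells, cfg, rng)
    boxes = (np.stack([c.bounding_box() for c in cells])
             if cells else np.zeros((0, 4)))
    ann = SceneAnnotation(
        image_id=image_id or f"scene_{seed:06d}",
        width=cfg.width, height=cfg.height, boxes=boxes,
        labels=[c.label for c in cells], seed=seed, config=asdict(cfg))
    return image, ann, cells


def generate_single_cell(config: SceneConfig | None = None, seed: int = 0,
                         label: str | None = None):
    """Single-cell crop (default 200x100) for the classifier regime."""
    base = config or SceneConfig(width=200, height=100, n_cells=1,
                                 cell_radius_range=(22.0, 40.0),
                                 overlap_allowance=0.0)
    rng = np.random.default_rng(seed)
    if label is None:
        label = ABNORMAL if rng.random() < base.abnormal_fraction else NORMAL
    cfg = SceneConfig(**{**asdict(base), "n_cells": 1,
                         "abnormal_fraction": 1.0 if label == ABNORMAL else 0.0})
    return generate_scene(cfg, seed=int(rng.integers(2**31)),
                          image_id=f"cell_{seed:06d}")


def resize_image(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Bilinear resize (aspect-distorting) of an HxWx3 uint8 image."""
    from PIL import Image

    return np.asarray(Image.fromarray(image).resize((width, height),
                                                    Image.BILINEAR))


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def split_counts(n: int, ratio: tuple[int, int, int] = (8, 1, 1)):
    """Train/val/test counts at the given ratio; remainder goes to train."""
    total = sum(ratio)
    n_val = n * ratio[1] // total
    n_test = n * ratio[2] // total
    return n - n_val - n_test, n_val, n_test


def generate_dataset(n_images: int, config: SceneConfig | None = None,
                     seed: int = 0, ratio=(8, 1, 1)):
    """Scenes split 8:1:1 into disjoint train/val/test sets.

    Returns {"train": [(image, annotation), ...], "val": ..., "test": ...};
    membership is deterministic under ``seed`` and image ids are unique
    across splits.
    """
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31, size=n_images)
    items = []
    for i, s in enumerate(scene_seeds):
        img, ann, _ = generate_scene(config, seed=int(s),
                                     image_id=f"img_{i:05d}")
        items.append((img, ann))
    order = rng.permutation(n_images)
    n_train, n_val, n_test = split_counts(n_images, ratio)
    splits = {
        "train": [items[i] for i in order[:n_train]],
        "val": [items[i] for i in order[n_train:n_train + n_val]],
        "test": [items[i] for i in order[n_train + n_val:]],
    }
    return splits


# --------------------------------------------------------------------------
# slide tiling
# --------------------------------------------------------------------------

@dataclass
class Tile:
    image: np.ndarray
    boxes: np.ndarray
    labels: list[str]
    origin: tuple[int, int]              # (x, y) of the tile in the slide
    index: tuple[int, int]               # (row, col) in the tile grid


def tile_grid_shape(width: int, height: int, tile: int = 800):
    """(rows, cols) of the non-overlapping tiling that covers the slide."""
    return math.ceil(height / tile), math.ceil(width / tile)


def tile_slide(image: np.ndarray, boxes: np.ndarray | None = None,
               labels: list[str] | None = None, tile: int = 800,
               min_box_frac: float = 0.3) -> list[Tile]:
    """Cut a slide into a non-overlapping ``tile`` x ``tile`` grid.

    Edge remainders are reflect-padded to full tile size.  Each box lands in
    every tile it intersects, clipped to the tile; a clipped box is dropped
    when its area falls below ``min_box_frac`` of the original.  Tile
    origins allow exact inverse mapping via :func:`tile_to_slide_box`.
    """
    h, w = image.shape[:2]
    if h < tile or w < tile:
        raise ValueError(f"slide {w}x{h} smaller than tile {tile}")
    boxes = np.zeros((0, 4)) if boxes is None else np.asarray(boxes, float)
    labels = labels or [""] * len(boxes)
    rows, cols = tile_grid_shape(w, h, tile)
    pad_h, pad_w = rows * tile - h, cols * tile - w
    padded = np.pad(image, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect") \
        if (pad_h or pad_w) else image
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    tiles = []
    for r in range(rows):
        for c in range(cols):
            x0, y0 = c * tile, r * tile
            sub = padded[y0:y0 + tile, x0:x0 + tile]
            keep_boxes, keep_labels = [], []
            for box, label, area in zip(boxes, labels, areas):
                cx0 = max(box[0], x0)
                cy0 = max(box[1], y0)
                cx1 = min(box[2], x0 + tile)
                cy1 = min(box[3], y0 + tile)
                if cx1 <= cx0 or cy1 <= cy0:
                    continue
                if (cx1 - cx0) * (cy1 - cy0) < min_box_frac * area:
                    continue
                keep_boxes.append([cx0 - x0, cy0 - y0, cx1 - x0, cy1 - y0])
                keep_labels.append(label)
            tiles.append(Tile(
                image=np.ascontiguousarray(sub),
                boxes=np.asarray(keep_boxes, float).reshape(-1, 4),
                labels=keep_labels, origin=(x0, y0), index=(r, c)))
    return tiles


def tile_to_slide_box(box, origin) -> np.ndarray:
    """Map a tile-local box back to slide coordinates."""
    box = np.asarray(box, float)
    return box + np.array([origin[0], origin[1], origin[0], origin[1]])


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def rot90_with_boxes(image: np.ndarray, boxes: np.ndarray, k: int = 1):
    """Rotate image + boxes by k*90 degrees counter-clockwise, exactly."""
    k = k % 4
    h, w = image.shape[:2]
    out = np.ascontiguousarray(np.rot90(image, k))
    b = np.asarray(boxes, float).reshape(-1, 4).copy()
    for _ in range(k):
        # (x, y) -> (y, w - x) for a 90-degree CCW turn of a WxH frame
        b = np.stack([b[:, 1], w - b[:, 2], b[:, 3], w - b[:, 0]], axis=1)
        h, w = w, h
    return out, b


def flip_with_boxes(image: np.ndarray, boxes: np.ndarray,
                    horizontal: bool = True):
    """Mirror image + boxes left-right (or top-bottom), exactly."""
    h, w = image.shape[:2]
    b = np.asarray(boxes, float).reshape(-1, 4).copy()
    if horizontal:
        out = np.ascontiguousarray(image[:, ::-1])
        b = np.stack([w - b[:, 2], b[:, 1], w - b[:, 0], b[:, 3]], axis=1)
    else:
        out = np.ascontiguousarray(image[::-1])
        b = np.stack([b[:, 0], h - b[:, 3], b[:, 2], h - b[:, 1]], axis=1)
    return out, b


def rotate_with_boxes(image: np.ndarray, boxes: np.ndarray, angle_deg: float,
                      order: int = 1):
    """Centre rotation by an arbitrary angle; boxes become the axis-aligned
    bound of their rotated corners, clipped to the frame."""
    from scipy import ndimage

    if angle_deg % 90 == 0:
        return rot90_with_boxes(image, boxes, int(angle_deg // 90))
    out = ndimage.rotate(image, angle_deg, reshape=False, order=order,
                         mode="reflect")
    h, w = image.shape[:2]
    cx, cy = w / 2.0, h / 2.0
    # image rotation by +angle corresponds to rotating content CCW;
    # a content point p maps to R(angle) @ (p - c) + c
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)],
                    [math.sin(t), math.cos(t)]])
    b = np.asarray(boxes, float).reshape(-1, 4)
    new = []
    for x0, y0, x1, y1 in b:
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]])
        moved = (corners - [cx, cy]) @ rot.T + [cx, cy]
        new.append([max(0.0, moved[:, 0].min()), max(0.0, moved[:, 1].min()),
                    min(float(w), moved[:, 0].max()),
                    min(float(h), moved[:, 1].max())])
    return out, np.asarray(new, float).reshape(-1, 4)


def augment_class_conditional(items, factors: dict[str, int]):
    """Replicate single-label items by centre rotation, per-class factors.

    ``items``: list of (image, label); a factor f yields f copies rotated at
    evenly spaced angles (the first copy is the 0-degree original).  Output
    per-class counts are exactly input counts times the class factor.
    """
    out = []
    for image, label in items:
        f = factors.get(label, 1)
        for j in range(f):
            angle = 360.0 * j / f
            if angle == 0.0:
                out.append((image, label))
            else:
                rotated, _ = rotate_with_boxes(image, np.zeros((0, 4)), angle)
                out.append((rotated, label))
    return out
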