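"""Synthetic cytology generator: determinism, label fidelity, tiling,
augmentation, annotation round-trips."""

import numpy as np
import pytest

from cytodet.io import (
    read_boxes_wh,
    read_coco_json,
    read_voc_xml,
    write_coco_json,
    write_voc_xml,
)
from cytodet.synthetic import (
    ABNORMAL,
    NORMAL,
    CellSpec,
    PackingError,
    SceneConfig,
    augment_class_conditional,
    flip_with_boxes,
    generate_dataset,
    generate_scene,
    generate_single_cell,
    render_cell_masks,
    resize_image,
    rot90_with_boxes,
    split_counts,
    tile_grid_shape,
    tile_slide,
    tile_to_slide_box,
)

SMALL = SceneConfig(width=160, height=160, n_cells=4,
                    cell_radius_range=(10.0, 22.0))


class TestSceneGeneration:
    def test_empty_scene(self):
        img, ann, cells = generate_scene(
            SceneConfig(width=64, height=64, n_cells=0), seed=0)
        assert img.shape == (64, 64, 3) and img.dtype == np.uint8
        assert len(ann.boxes) == 0 and cells == []

    def test_seed_determinism_bitwise(self):
        a_img, a_ann, _ = generate_scene(SMALL, seed=42)
        b_img, b_ann, _ = generate_scene(SMALL, seed=42)
        np.testing.assert_array_equal(a_img, b_img)
        np.testing.assert_array_equal(a_ann.boxes, b_ann.boxes)
        assert a_ann.labels == b_ann.labels

    def test_exact_class_mix_and_one_box_per_cell(self):
        cfg = SceneConfig(width=400, height=400, n_cells=20,
                          abnormal_fraction=0.5,
                          cell_radius_range=(8.0, 16.0))
        _, ann, cells = generate_scene(cfg, seed=1)
        assert len(ann.boxes) == 20 == len(cells)
        assert sum(l == ABNORMAL for l in ann.labels) == 10
        assert sum(l == NORMAL for l in ann.labels) == 10

    def test_boxes_tight_and_within_bounds(self):
        _, ann, cells = generate_scene(SMALL, seed=3)
        assert np.all(ann.boxes[:, 0] >= 0) and np.all(ann.boxes[:, 1] >= 0)
        assert np.all(ann.boxes[:, 2] <= SMALL.width)
        assert np.all(ann.boxes[:, 3] <= SMALL.height)
        for box, cell in zip(ann.boxes, cells):
            cyto, _ = render_cell_masks(cell, SMALL.height, SMALL.width)
            ys, xs = np.nonzero(cyto)
            # rendered support inside the declared box (half-pixel slack)
            assert xs.min() + 0.5 >= box[0] - 0.5
            assert xs.max() + 0.5 <= box[2] + 0.5
            assert ys.min() + 0.5 >= box[1] - 0.5
            assert ys.max() + 0.5 <= box[3] + 0.5

    def test_label_recoverable_from_rendered_masks(self):
        """The nucleus/cytoplasm area ratio measured on the rendered masks
        reproduces every cell's assigned class."""
        cfg = SceneConfig(width=300, height=300, n_cells=10,
                          cell_radius_range=(12.0, 30.0))
        for seed in (0, 1, 2):
            _, ann, cells = generate_scene(cfg, seed=seed)
            for cell in cells:
                cyto, nuc = render_cell_masks(cell, cfg.height, cfg.width)
                measured = nuc.sum() / cyto.sum()
                derived = ABNORMAL if measured > cfg.ratio_threshold else NORMAL
                assert derived == cell.label

    def test_infeasible_packing_raises(self):
        cfg = SceneConfig(width=80, height=80, n_cells=30,
                          cell_radius_range=(20.0, 25.0),
                          overlap_allowance=0.0, max_place_attempts=40)
        with pytest.raises(PackingError):
            generate_scene(cfg, seed=0)

    def test_nucleus_containment_enforced(self):
        with pytest.raises(ValueError):
            CellSpec((10, 10), (5.0, 4.0), (6.0, 3.0), 0.0, NORMAL)

    def test_single_cell_regime_shape_and_resize(self):
        img, ann, cells = generate_single_cell(seed=5, label=ABNORMAL)
        assert img.shape == (100, 200, 3)
        assert len(cells) == 1 and cells[0].label == ABNORMAL
        up = resize_image(img, 224, 224)
        assert up.shape == (224, 224, 3)


class TestDataset:
    def test_split_counts_ratio(self):
        assert split_counts(100) == (80, 10, 10)
        assert split_counts(17) == (15, 1, 1)

    def test_dataset_split_membership_and_determinism(self):
        cfg = SceneConfig(width=96, height=96, n_cells=2,
                          cell_radius_range=(8.0, 14.0))
        splits = generate_dataset(10, cfg, seed=7)
        assert [len(splits[s]) for s in ("train", "val", "test")] == [8, 1, 1]
        ids = [ann.image_id for s in splits.values() for _, ann in s]
        assert len(set(ids)) == 10
        again = generate_dataset(10, cfg, seed=7)
        assert [ann.image_id for _, ann in again["test"]] \
            == [ann.image_id for _, ann in splits["test"]]


class TestTiling:
    def test_grid_shape_matches_ceiling_arithmetic(self):
        # the slide-scale case: ceil(42371/800) x ceil(40835/800) = 53 x 52
        rows, cols = tile_grid_shape(40835, 42371, 800)
        assert (rows, cols) == (53, 52)
        assert rows * cols == 2756

    def test_single_tile_passthrough(self):
        img, ann, _ = generate_scene(SMALL, seed=2)
        tiles = tile_slide(img, ann.boxes, ann.labels, tile=160)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].image, img)
        np.testing.assert_allclose(tiles[0].boxes, ann.boxes)

    def test_every_pixel_in_exactly_one_tile(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (70, 90, 3), dtype=np.uint8)
        tiles = tile_slide(img, tile=32)
        recon = np.zeros((96, 96, 3), np.uint8)
        counts = np.zeros((96, 96), int)
        for t in tiles:
            x, y = t.origin
            recon[y:y + 32, x:x + 32] = t.image
            counts[y:y + 32, x:x + 32] += 1
        assert counts.max() == counts.min() == 1
        np.testing.assert_array_equal(recon[:70, :90], img)

    def test_box_roundtrip_and_edge_drop_policy(self):
        img = np.zeros((64, 96, 3), np.uint8)
        inner = np.array([[40.0, 10.0, 60.0, 30.0]])       # fully in tile (1,0..)
        straddle = np.array([[28.0, 8.0, 36.0, 16.0]])     # 50/50 across x=32
        sliver = np.array([[30.0, 8.0, 50.0, 16.0]])       # 10% in left tile
        boxes = np.vstack([inner, straddle, sliver])
        tiles = tile_slide(img, boxes, ["a", "b", "c"], tile=32,
                           min_box_frac=0.3)
        by_index = {t.index: t for t in tiles}
        t10 = by_index[(0, 1)]
        assert "a" in t10.labels
        local = t10.boxes[t10.labels.index("a")]
        np.testing.assert_allclose(
            tile_to_slide_box(local, t10.origin), inner[0])
        # the straddling box (50% each side) is kept in both x-tiles
        t00 = by_index[(0, 0)]
        assert t00.labels.count("b") == 1 and t10.labels.count("b") == 1
        # the sliver (10% in the left tile) is dropped there, kept right
        assert "c" not in t00.labels and "c" in t10.labels

    def test_too_small_slide_rejected(self):
        with pytest.raises(ValueError):
            tile_slide(np.zeros((16, 200, 3), np.uint8), tile=32)


class TestAugmentation:
    def test_rot90_shape_and_exact_box_mapping(self):
        img, ann, _ = generate_scene(SMALL, seed=9)
        h, w = img.shape[:2]
        out, boxes = rot90_with_boxes(img, ann.boxes, k=1)
        assert out.shape[:2] == (w, h)
        # rotating four times is the identity
        img4, boxes4 = img, ann.boxes
        for _ in range(4):
            img4, boxes4 = rot90_with_boxes(img4, boxes4, k=1)
        np.testing.assert_array_equal(img4, img)
        np.testing.assert_allclose(boxes4, ann.boxes)
        # pixel-content check: a marked pixel follows its box
        probe = np.zeros((8, 6, 3), np.uint8)
        probe[1, 4] = 255
        pbox = np.array([[4.0, 1.0, 5.0, 2.0]])
        rot, rbox = rot90_with_boxes(probe, pbox, k=1)
        ys, xs = np.nonzero(rot[..., 0])
        assert (xs[0] + 0.5, ys[0] + 0.5) == \
            ((rbox[0, 0] + rbox[0, 2]) / 2, (rbox[0, 1] + rbox[0, 3]) / 2)

    def test_flip_involution(self):
        img, ann, _ = generate_scene(SMALL, seed=10)
        for horizontal in (True, False):
            f_img, f_box = flip_with_boxes(img, ann.boxes, horizontal)
            ff_img, ff_box = flip_with_boxes(f_img, f_box, horizontal)
            np.testing.assert_array_equal(ff_img, img)
            np.testing.assert_allclose(ff_box, ann.boxes)

    def test_class_conditional_replication_factors(self):
        items = []
        for seed in range(3):
            img, _, cells = generate_single_cell(seed=seed, label=NORMAL)
            items.append((img, NORMAL))
        for seed in range(2):
            img, _, cells = generate_single_cell(seed=10 + seed,
                                                 label=ABNORMAL)
            items.append((img, ABNORMAL))
        out = augment_class_conditional(items, {NORMAL: 20, ABNORMAL: 10})
        labels = [l for _, l in out]
        assert labels.count(NORMAL) == 3 * 20
        assert labels.count(ABNORMAL) == 2 * 10


class TestAnnotationIO:
    def test_voc_roundtrip(self, tmp_path):
        _, ann, _ = generate_scene(SMALL, seed=11)
        path = tmp_path / f"{ann.image_id}.xml"
        write_voc_xml(ann, path)
        back = read_voc_xml(path)
        assert back.image_id == ann.image_id
        assert (back.width, back.height) == (ann.width, ann.height)
        np.testing.assert_allclose(back.boxes, ann.boxes, atol=0.01)
        assert back.labels == ann.labels

    def test_coco_roundtrip_multiple_images(self, tmp_path):
        anns = [generate_scene(SMALL, seed=s)[1] for s in (1, 2, 3)]
        path = tmp_path / "set.json"
        write_coco_json(anns, path)
        back = read_coco_json(path)
        assert [b.image_id for b in back] == [a.image_id for a in anns]
        for a, b in zip(anns, back):
            np.testing.assert_allclose(b.boxes, a.boxes, atol=1e-9)
            assert b.labels == a.labels

    def test_read_boxes_wh_from_both_formats(self, tmp_path):
        anns = [generate_scene(SMALL, seed=s)[1] for s in (4, 5)]
        for a in anns:
            write_voc_xml(a, tmp_path / f"{a.image_id}.xml")
        write_coco_json(anns, tmp_path / "set.json")
        n_boxes = sum(len(a.boxes) for a in anns)
        wh_dir = read_boxes_wh(tmp_path)
        wh_json = read_boxes_wh(tmp_path / "set.json")
        assert wh_dir.shape == wh_json.shape == (n_boxes, 2)
        np.testing.assert_allclose(np.sort(wh_dir, axis=0),
                                   np.sort(wh_json, axis=0), atol=0.02)
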