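"""Readers/writers for annotation and result formats.

Annotations travel as Pascal VOC XML (one file per image) or COCO JSON (one
file per set); anchors as YAML; detections as COCO-result JSON or CSV.
Boxes are [x_min, y_min, x_max, y_max] floats in pixel units, half-open.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import yaml

from .anchors import AnchorSet
from .synthetic import SceneAnnotation


# --------------------------------------------------------------------------
# Pascal VOC XML
# --------------------------------------------------------------------------

def write_voc_xml(ann: SceneAnnotation, path: str | Path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    for box, label in zip(ann.boxes, ann.labels):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = f"{box[0]:.2f}"
        ET.SubElement(bnd, "ymin").text = f"{box[1]:.2f}"
        ET.SubElement(bnd, "xmax").text = f"{box[2]:.2f}"
        ET.SubElement(bnd, "ymax").text = f"{box[3]:.2f}"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def read_voc_xml(path: str | Path) -> SceneAnnotation:
    root = ET.parse(path).getroot()
    size = root.find("size")
    boxes, labels = [], []
    for obj in root.findall("object"):
        bnd = obj.find("bndbox")
        boxes.append([float(bnd.find(tag).text)
                      for tag in ("xmin", "ymin", "xmax", "ymax")])
        labels.append(obj.find("name").text)
    image_id = Path(root.findtext("filename", default=Path(path).stem)).stem
    return SceneAnnotation(
        image_id=image_id,
        width=int(size.find("width").text),
        height=int(size.find("height").text),
        boxes=np.asarray(boxes, float).reshape(-1, 4),
        labels=labels, seed=-1)


# --------------------------------------------------------------------------
# COCO JSON
# --------------------------------------------------------------------------

def write_coco_json(annotations: list[SceneAnnotation], path: str | Path,
                    categories: list[str] = ("normal", "abnormal")) -> None:
    cat_id = {name: i + 1 for i, name in enumerate(categories)}
    images, annos = [], []
    next_ann = 1
    for img_idx, ann in enumerate(annotations, start=1):
        images.append({"id": img_idx, "file_name": f"{ann.image_id}.png",
                       "width": ann.width, "height": ann.height})
        for box, label in zip(ann.boxes, ann.labels):
            x0, y0, x1, y1 = (float(v) for v in box)
            annos.append({
                "id": next_ann, "image_id": img_idx,
                "category_id": cat_id[label],
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0),
                "iscrowd": 0,
            })
            next_ann += 1
    doc = {
        "images": images,
        "annotations": annos,
        "categories": [{"id": i, "name": n} for n, i in cat_id.items()],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_json(path: str | Path) -> list[SceneAnnotation]:
    doc = json.loads(Path(path).read_text())
    cat_name = {c["id"]: c["name"] for c in doc["categories"]}
    per_image: dict[int, list] = {img["id"]: [] for img in doc["images"]}
    for a in doc["annotations"]:
        x, y, w, h = a["bbox"]
        per_image[a["image_id"]].append(
            ([x, y, x + w, y + h], cat_name[a["category_id"]]))
    out = []
    for img in doc["images"]:
        entries = per_image[img["id"]]
        out.append(SceneAnnotation(
            image_id=Path(img["file_name"]).stem,
            width=img["width"], height=img["height"],
            boxes=np.asarray([e[0] for e in entries],
                             float).reshape(-1, 4),
            labels=[e[1] for e in entries], seed=-1))
    return out


def read_boxes_wh(path: str | Path) -> np.ndarray:
    """All annotation (w, h) pairs from a VOC XML file, a directory of VOC
    XML files, or a COCO JSON file — the clustering input."""
    path = Path(path)
    if path.is_dir():
        anns = [read_voc_xml(p) for p in sorted(path.glob("*.xml"))]
    elif path.suffix.lower() == ".json":
        anns = read_coco_json(path)
    else:
        anns = [read_voc_xml(path)]
    wh = [np.stack([a.boxes[:, 2] - a.boxes[:, 0],
                    a.boxes[:, 3] - a.boxes[:, 1]], axis=1)
          for a in anns if len(a.boxes)]
    return np.concatenate(wh) if wh else np.zeros((0, 2))


# --------------------------------------------------------------------------
# anchors YAML
# --------------------------------------------------------------------------

def write_anchors_yaml(anchors: AnchorSet, path: str | Path) -> None:
    doc = {
        "k": anchors.k,
        "avg_iou": float(anchors.avg_iou),
        "objective": float(anchors.objective),
        "shapes": [[float(w), float(h)] for w, h in anchors.shapes],
    }
    if anchors.per_level is not None:
        doc["per_level"] = [[[float(w), float(h)] for w, h in level]
                            for level in anchors.per_level]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_anchors_yaml(path: str | Path) -> AnchorSet:
    doc = yaml.safe_load(Path(path).read_text())
    return AnchorSet(
        k=doc["k"], shapes=np.asarray(doc["shapes"], float),
        avg_iou=doc["avg_iou"], objective=doc["objective"],
        per_level=[np.asarray(lv, float) for lv in doc["per_level"]]
        if "per_level" in doc else None)


# --------------------------------------------------------------------------
# detections
# --------------------------------------------------------------------------

def write_detections_csv(rows, path: str | Path) -> None:
    """rows: iterable of (image_id, class, score, x_min, y_min, x_max, y_max)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "class", "score",
                         "x_min", "y_min", "x_max", "y_max"])
        for row in rows:
            writer.writerow(row)


def write_detections_coco(rows, path: str | Path,
                          categories: list[str] = ("normal", "abnormal")) -> None:
    cat_id = {name: i + 1 for i, name in enumerate(categories)}
    out = []
    for image_id, cls, score, x0, y0, x1, y1 in rows:
        out.append({
            "image_id": image_id, "category_id": cat_id[cls],
            "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
            "score": float(score),
        })
    Path(path).write_text(json.dumps(out, indent=1))


def save_image_png(image: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(image).save(path)


def load_image(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))
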