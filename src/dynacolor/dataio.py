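"""File formats: annotation CSV, COCO-style JSON, prediction CSV, config.

The native annotation dialect (``box_csv``) is a CSV with columns
``image_name, domain, boxes`` where ``boxes`` is a semicolon-separated
list of ``x_min y_min x_max y_max`` quadruples in 0-based pixel
coordinates; an empty field means an image with no boxes.  A
COCO-style JSON export (1-indexed ids, ``[x, y, width, height]``
boxes) is provided for interoperability, converted explicitly at the
boundary.  Predictions are one row per detection with the confidence
printed to 6 decimals, ordered by image name then descending
confidence, so repeated writes are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .toy_detector import Box, Detection

__all__ = [
    "AnnotationRecord", "read_annotations", "write_annotations",
    "read_predictions", "write_predictions", "annotations_to_coco",
    "coco_to_annotations", "load_image", "save_image", "load_config",
    "config_hash", "log_header",
]

DIALECTS = ("box_csv", "coco_json")


@dataclass
class AnnotationRecord:
    image_name: str
    domain: str
    boxes: list[Box]


def _parse_boxes(text, line_no: int) -> list[Box]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    boxes = []
    for part in text.split(";"):
        vals = part.split()
        if len(vals) != 4:
            raise ValueError(
                f"line {line_no}: box {part!r} does not have 4 coordinates")
        try:
            coords = [float(v) for v in vals]
        except ValueError as exc:
            raise ValueError(
                f"line {line_no}: non-numeric box {part!r}") from exc
        try:
            boxes.append(Box(*coords))
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    return boxes


def _format_boxes(boxes) -> str:
    return ";".join(
        f"{b.x_min:g} {b.y_min:g} {b.x_max:g} {b.y_max:g}" for b in boxes)


def read_annotations(path, dialect: str = "box_csv") -> list[AnnotationRecord]:
    """Parse an annotation file into records (boxes validated)."""
    if dialect == "box_csv":
        df = pd.read_csv(path, dtype={"image_name": str, "domain": str},
                         keep_default_na=False)
        records = []
        for i, row in df.iterrows():
            records.append(AnnotationRecord(
                image_name=row["image_name"], domain=row["domain"],
                boxes=_parse_boxes(row["boxes"], line_no=i + 2)))
        return records
    if dialect == "coco_json":
        with open(path) as fh:
            return coco_to_annotations(json.load(fh))
    raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")


def write_annotations(records: list[AnnotationRecord], path,
                      dialect: str = "box_csv") -> None:
    if dialect == "box_csv":
        df = pd.DataFrame({
            "image_name": [r.image_name for r in records],
            "domain": [r.domain for r in records],
            "boxes": [_format_boxes(r.boxes) for r in records],
        })
        df.to_csv(path, index=False)
        return
    if dialect == "coco_json":
        with open(path, "w") as fh:
            json.dump(annotations_to_coco(records), fh, indent=1,
                      sort_keys=True)
        return
    raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")


def annotations_to_coco(records: list[AnnotationRecord]) -> dict:
    """Convert records to a COCO-style dict (1-indexed, xywh boxes)."""
    images, annotations = [], []
    ann_id = 1
    for img_id, r in enumerate(records, start=1):
        images.append({"id": img_id, "file_name": r.image_name,
                       "domain": r.domain})
        for b in r.boxes:
            annotations.append({
                "id": ann_id, "image_id": img_id, "category_id": 1,
                "bbox": [b.x_min, b.y_min, b.x_max - b.x_min,
                         b.y_max - b.y_min],
                "area": b.area, "iscrowd": 0,
            })
            ann_id += 1
    return {"images": images, "annotations": annotations,
            "categories": [{"id": 1, "name": "head"}]}


def coco_to_annotations(coco: dict) -> list[AnnotationRecord]:
    by_image = {im["id"]: AnnotationRecord(
        image_name=im["file_name"], domain=im.get("domain", ""), boxes=[])
        for im in coco["images"]}
    for ann in coco.get("annotations", []):
        x, y, w, h = ann["bbox"]
        by_image[ann["image_id"]].boxes.append(Box(x, y, x + w, y + h))
    return [by_image[k] for k in sorted(by_image)]


def write_predictions(detections_per_image: dict, path) -> None:
    """Write {image_name: [Detection, ...]} to a prediction CSV.

    Deterministic: rows sorted by image name then descending
    confidence, confidences with 6 decimals.  Images with no
    detections still appear via the header-only convention (no rows).
    """
    rows = []
    for name in sorted(detections_per_image):
        dets = sorted(detections_per_image[name],
                      key=lambda d: -d.confidence)
        for d in dets:
            rows.append({
                "image_name": name,
                "x_min": f"{d.box.x_min:.6f}", "y_min": f"{d.box.y_min:.6f}",
                "x_max": f"{d.box.x_max:.6f}", "y_max": f"{d.box.y_max:.6f}",
                "confidence": f"{d.confidence:.6f}",
                "class_label": d.class_label,
            })
    cols = ["image_name", "x_min", "y_min", "x_max", "y_max",
            "confidence", "class_label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_predictions(path) -> dict:
    df = pd.read_csv(path, dtype={"image_name": str})
    out: dict[str, list[Detection]] = {}
    for _, row in df.iterrows():
        det = Detection(
            box=Box(row["x_min"], row["y_min"], row["x_max"], row["y_max"]),
            confidence=float(row["confidence"]),
            class_label=int(row["class_label"]))
        out.setdefault(row["image_name"], []).append(det)
    return out


# ---------------------------------------------------------------------------
# images and config

def save_image(image: np.ndarray, path) -> None:
    """Write a [0,1] float image as 8-bit PNG."""
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).round().astype(np.uint8)
    iio.imwrite(path, arr)


def load_image(path) -> np.ndarray:
    """Read an image and normalize intensities to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr.astype(np.float64) / 255.0


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def log_header(seed, config) -> str:
    """Reproducibility header written at the top of every run log."""
    from . import __version__
    return (f"# dynacolor {__version__} seed={seed} "
            f"config_hash={config_hash(config)}")
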