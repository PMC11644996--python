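"""Core data containers and COCO detection JSON round-tripping.

Boxes are kept internally as 0-based half-open corners
``[x_min, y_min, x_max, y_max]`` and converted to COCO's
``[x, y, width, height]`` only at (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Annotation", "CellPatch", "ImageSample", "DetectionDataset", "Prediction",
    "FormatError", "corners_to_xywh", "xywh_to_corners",
    "read_coco", "write_coco",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected schema."""


def corners_to_xywh(box) -> list:
    x0, y0, x1, y1 = box
    return [float(x0), float(y0), float(x1 - x0), float(y1 - y0)]


def xywh_to_corners(box) -> np.ndarray:
    x, y, w, h = box
    return np.array([x, y, x + w, y + h], dtype=float)


@dataclass
class Annotation:
    bbox: np.ndarray  # [x_min, y_min, x_max, y_max], half-open
    class_id: int

    def __post_init__(self):
        self.bbox = np.asarray(self.bbox, dtype=float)
        if self.bbox.shape != (4,):
            raise ValueError("bbox must have 4 entries")


@dataclass
class ImageSample:
    image: np.ndarray  # (H, W, 3) uint8
    annotations: list = field(default_factory=list)
    image_id: int = 0
    provenance: str = "real"  # "real" | "synthetic"
    file_name: str | None = None

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass
class CellPatch:
    """An RGBA cutout of one cell.

    `alpha` is the per-pixel opacity in [0, 1]; before any augmentation it is
    exactly the source segmentation mask restricted to the crop.
    """

    rgb: np.ndarray            # (h, w, 3) uint8
    alpha: np.ndarray          # (h, w) float in [0, 1]
    class_id: int
    provenance: str = ""       # e.g. "fixture:<image_id>:<bbox>"

    def __post_init__(self):
        if self.rgb.shape[:2] != self.alpha.shape:
            raise ValueError("rgb and alpha must share height x width")
        if not (self.alpha > 0).any():
            raise ValueError("alpha must be positive somewhere")

    @property
    def mask(self) -> np.ndarray:
        """Boolean support of the patch (alpha > 0.5)."""
        return self.alpha > 0.5


@dataclass
class Prediction:
    """Scored boxes for one image."""

    boxes: np.ndarray         # (M, 4) corners
    scores: np.ndarray        # (M,)
    class_ids: np.ndarray     # (M,) int
    image_id: int = 0
    class_probs: np.ndarray | None = None  # (M, K+1) rows summing to 1

    def __len__(self):
        return len(self.scores)


@dataclass
class DetectionDataset:
    samples: list
    class_names: list

    def __len__(self):
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_annotations(self) -> int:
        return sum(len(s.annotations) for s in self.samples)

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.class_names), dtype=int)
        for s in self.samples:
            for a in s.annotations:
                counts[a.class_id] += 1
        return counts

    # -- COCO serialization -------------------------------------------
    def to_coco(self) -> dict:
        images, annotations = [], []
        ann_id = 1
        for s in self.samples:
            images.append({
                "id": int(s.image_id),
                "width": int(s.width),
                "height": int(s.height),
                "file_name": s.file_name or f"{s.image_id:06d}.png",
                "provenance": s.provenance,
            })
            for a in s.annotations:
                xywh = corners_to_xywh(a.bbox)
                annotations.append({
                    "id": ann_id,
                    "image_id": int(s.image_id),
                    "category_id": int(a.class_id) + 1,
                    "bbox": xywh,
                    "area": xywh[2] * xywh[3],
                    "iscrowd": 0,
                })
                ann_id += 1
        categories = [{"id": i + 1, "name": n} for i, n in enumerate(self.class_names)]
        return {"images": images, "annotations": annotations, "categories": categories}

    def canonical_json(self) -> str:
        return json.dumps(self.to_coco(), sort_keys=True, separators=(",", ":"))


def _require(cond: bool, path: str, msg: str):
    if not cond:
        raise FormatError(f"{path}: {msg}")


def read_coco(path, image_dir=None) -> DetectionDataset:
    """Load a COCO detection JSON; pixel data is read from `image_dir` if given.

    Raises :class:`FormatError` naming the offending JSON path on schema
    violations (missing keys, dangling image references).
    """
    import imageio.v3 as iio

    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        _require(key in doc, f"$.{key}", "missing required key")
    cats = sorted(doc["categories"], key=lambda c: c["id"])
    _require(all("id" in c and "name" in c for c in cats), "$.categories", "entries need id and name")
    cat_to_class = {c["id"]: i for i, c in enumerate(cats)}
    class_names = [c["name"] for c in cats]

    samples = {}
    for i, rec in enumerate(doc["images"]):
        _require("id" in rec, f"$.images[{i}]", "missing id")
        h, w = int(rec.get("height", 0)), int(rec.get("width", 0))
        if image_dir is not None:
            img = np.asarray(iio.imread(Path(image_dir) / rec["file_name"]))
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=-1)
            img = img[..., :3]
        else:
            img = np.zeros((h, w, 3), dtype=np.uint8)
        samples[rec["id"]] = ImageSample(
            image=img, annotations=[], image_id=int(rec["id"]),
            provenance=rec.get("provenance", "real"),
            file_name=rec.get("file_name"),
        )
    for i, ann in enumerate(doc["annotations"]):
        loc = f"$.annotations[{i}]"
        _require("image_id" in ann and "bbox" in ann and "category_id" in ann,
                 loc, "missing image_id/bbox/category_id")
        _require(ann["image_id"] in samples, f"{loc}.image_id",
                 f"references missing image id {ann['image_id']}")
        _require(ann["category_id"] in cat_to_class, f"{loc}.category_id",
                 f"references missing category id {ann['category_id']}")
        samples[ann["image_id"]].annotations.append(
            Annotation(bbox=xywh_to_corners(ann["bbox"]),
                       class_id=cat_to_class[ann["category_id"]]))
    ordered = [samples[rec["id"]] for rec in doc["images"]]
    return DetectionDataset(samples=ordered, class_names=class_names)


def write_coco(dataset: DetectionDataset, path, image_dir=None):
    """Write the annotation JSON; also write PNGs when `image_dir` is given."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    for s in dataset.samples:
        s.file_name = s.file_name or f"{s.image_id:06d}.png"
    with open(path, "w") as fh:
        fh.write(dataset.canonical_json())
    if image_dir is not None:
        image_dir = Path(image_dir)
        image_dir.mkdir(parents=True, exist_ok=True)
        for s in dataset.samples:
            iio.imwrite(image_dir / s.file_name, s.image)
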