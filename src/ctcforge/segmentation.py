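"""Per-cell instance masks from images, via pluggable backends.

The mandatory backend is classical (Otsu threshold, morphological opening,
connected components, area filter) and fully deterministic. A promptable
foundation-model backend (Segment Anything) can be plugged in when its
package and weights are available; it is never required by the rest of the
toolkit, and all downstream code consumes the same :class:`MaskSet` type
regardless of backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening

from .data import ImageSample
from .errors import BackendError, EmptyMaskError

__all__ = ["MaskSet", "ClassicalBackend", "SamBackend", "classical_segment",
           "segment_cells", "mask_to_bbox", "masks_to_label_image", "mask_to_rle",
           "rle_to_mask"]


@dataclass
class MaskSet:
    masks: list                  # boolean arrays, image-sized, descending area
    source_image_id: int = 0
    backend_name: str = "classical"

    def __len__(self):
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)


def mask_to_bbox(mask: np.ndarray) -> np.ndarray:
    """Tight half-open [x_min, y_min, x_max, y_max] over foreground pixels."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=float)


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image.astype(float).mean(axis=2)
    return image.astype(float)


def _sort_masks(masks: list) -> list:
    def key(m):
        ys, xs = np.nonzero(m)
        order = np.lexsort((xs, ys))
        return (-int(m.sum()), int(ys[order[0]]), int(xs[order[0]]))
    return sorted(masks, key=key)


def classical_segment(image, min_area: int = 25, morphology_radius: int = 2,
                      polarity: str = "auto") -> MaskSet:
    """Otsu threshold -> morphological opening -> connected components -> area filter.

    `polarity` selects which side of the threshold is foreground:
    ``bright_on_dark`` (fluorescence), ``dark_on_bright`` (light-field) or
    ``auto``, which picks the side with the smaller foreground fraction
    (cells are sparse by assumption).
    """
    if polarity not in ("bright_on_dark", "dark_on_bright", "auto"):
        raise ValueError(f"unknown polarity {polarity!r}")
    img = image.image if isinstance(image, ImageSample) else image
    image_id = image.image_id if isinstance(image, ImageSample) else 0
    gray = _to_gray(img)
    if np.ptp(gray) == 0:  # uniform image: no foreground
        return MaskSet(masks=[], source_image_id=image_id)
    thr = threshold_otsu(gray)
    bright = gray > thr
    dark = gray <= thr
    if polarity == "bright_on_dark":
        fg = bright
    elif polarity == "dark_on_bright":
        fg = dark
    else:
        fg = bright if bright.mean() <= dark.mean() else dark
    if morphology_radius > 0:
        fg = opening(fg, disk(morphology_radius))
    labels = cc_label(fg, connectivity=2)
    masks = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if m.sum() >= min_area:
            masks.append(m)
    return MaskSet(masks=_sort_masks(masks), source_image_id=image_id)


class ClassicalBackend:
    """Deterministic threshold-based segmentation backend."""

    name = "classical"

    def __init__(self, min_area: int = 25, morphology_radius: int = 2,
                 polarity: str = "auto"):
        self.min_area = min_area
        self.morphology_radius = morphology_radius
        self.polarity = polarity

    def segment(self, image) -> MaskSet:
        ms = classical_segment(image, self.min_area, self.morphology_radius,
                               self.polarity)
        ms.backend_name = self.name
        return ms


class SamBackend:
    """Adapter for the Segment Anything model (optional plug-in).

    Supports automatic mask generation (no prompt) and box prompts. The
    heavyweight dependency and its checkpoint are loaded lazily; when either
    is missing a :class:`BackendError` naming the classical fallback is
    raised instead of a bare ImportError.
    """

    name = "sam"

    def __init__(self, checkpoint_path=None, model_type: str = "vit_b",
                 mode: str = "automatic", min_area: int = 25):
        self.checkpoint_path = checkpoint_path
        self.model_type = model_type
        if mode not in ("automatic", "box_prompt"):
            raise ValueError("mode must be 'automatic' or 'box_prompt'")
        self.mode = mode
        self.min_area = min_area
        self._predictor = None

    def _load(self):
        if self._predictor is not None:
            return
        try:
            import segment_anything  # noqa: F401
        except ImportError as exc:
            raise BackendError(
                "segment-anything is not installed; use the classical backend "
                "(ClassicalBackend / --backend classical) instead") from exc
        if self.checkpoint_path is None:
            raise BackendError(
                "no SAM checkpoint configured; use the classical backend instead")
        from segment_anything import (SamAutomaticMaskGenerator, SamPredictor,
                                      sam_model_registry)
        sam = sam_model_registry[self.model_type](checkpoint=str(self.checkpoint_path))
        self._predictor = (SamAutomaticMaskGenerator(sam) if self.mode == "automatic"
                           else SamPredictor(sam))

    def segment(self, image, boxes=None) -> MaskSet:
        self._load()
        img = image.image if isinstance(image, ImageSample) else image
        image_id = image.image_id if isinstance(image, ImageSample) else 0
        if self.mode == "automatic":
            raw = self._predictor.generate(img)
            records = sorted(raw, key=lambda r: -r.get("predicted_iou", 0.0))
            masks = [np.asarray(r["segmentation"], dtype=bool) for r in records]
        else:
            if boxes is None:
                raise ValueError("box_prompt mode requires boxes")
            self._predictor.set_image(img)
            masks = []
            for box in boxes:
                m, _, _ = self._predictor.predict(box=np.asarray(box), multimask_output=False)
                masks.append(np.asarray(m[0], dtype=bool))
        masks = _resolve_overlaps(masks)
        masks = [m for m in masks if m.sum() >= self.min_area]
        return MaskSet(masks=_sort_masks(masks), source_image_id=image_id,
                       backend_name=self.name)


def _resolve_overlaps(masks: list) -> list:
    """Keep higher-confidence masks intact; subtract them from later ones."""
    out, occupied = [], None
    for m in masks:
        m = m if occupied is None else (m & ~occupied)
        if m.any():
            out.append(m)
            occupied = m if occupied is None else (occupied | m)
    return out


def segment_cells(image, backend=None, **params) -> MaskSet:
    """Segment one image with the given backend (default: classical)."""
    if backend is None or backend == "classical":
        backend = ClassicalBackend(**params)
    elif backend == "sam":
        backend = SamBackend(**params)
    return backend.segment(image)


# -- mask serialization helpers ---------------------------------------
def masks_to_label_image(maskset: MaskSet, shape=None) -> np.ndarray:
    """Integer label image: 0 background, i = i-th mask (1-based)."""
    if shape is None:
        if not maskset.masks:
            raise ValueError("cannot infer shape from an empty MaskSet")
        shape = maskset.masks[0].shape
    out = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(maskset.masks, start=1):
        out[m] = i
    return out


def mask_to_rle(mask: np.ndarray) -> dict:
    """COCO-style uncompressed RLE (column-major counts, starting with 0s)."""
    flat = np.asarray(mask, dtype=bool).T.ravel()
    counts, prev, run = [], False, 0
    for v in flat:
        if v == prev:
            run += 1
        else:
            counts.append(run)
            prev, run = v, 1
    counts.append(run)
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    return flat.reshape(w, h).T
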