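"""Seeded synthetic microscopy fixtures with exact ground truth.

Generates light-field-like (dark cells on a bright background) or
fluorescence-like (bright cells on a dark background) images of
ellipse-derived blobs with sinusoidally perturbed boundaries, together with
pixel-exact masks and tight bounding boxes. Every operation is a pure
function of (config, seed), so the whole toolkit is testable without any
external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import Annotation, CellPatch, DetectionDataset, ImageSample
from .errors import CapacityError, ConfigurationError

__all__ = ["FixtureConfig", "GroundTruthInstance", "make_background",
           "make_cell", "make_detection_dataset", "make_patch_bank",
           "default_class_names"]

_CLASS_NAMES = ["ctc", "wbc", "rbc", "platelet"]


def default_class_names(n: int) -> list:
    return [_CLASS_NAMES[i] if i < len(_CLASS_NAMES) else f"cell{i}" for i in range(n)]


@dataclass(frozen=True)
class FixtureConfig:
    image_size: int = 128
    n_images: int = 20
    cells_per_image: tuple = (1, 4)        # inclusive integer range
    n_classes: int = 2
    cell_radius: tuple = (6.0, 14.0)       # semi-major axis range, px
    cell_eccentricity: tuple = (0.0, 0.6)  # range in [0, 1)
    boundary_irregularity: float = 0.15    # relative radial amplitude
    contrast: float = 120.0                # min fg/bg mean intensity gap
    modality: str = "lightfield"           # or "fluorescence"
    background_noise_sigma: float = 5.0    # 8-bit intensity units
    shading_amplitude: float = 6.0         # low-frequency background shading
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ConfigurationError("image_size too small")
        if self.modality not in ("lightfield", "fluorescence"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.background_noise_sigma < 0:
            raise ConfigurationError("background_noise_sigma must be >= 0")
        if self.boundary_irregularity < 0:
            raise ConfigurationError("boundary_irregularity must be >= 0")
        if not (0 <= self.cell_eccentricity[0] <= self.cell_eccentricity[1] < 1):
            raise ConfigurationError("cell_eccentricity must lie in [0, 1)")
        if 2 * self.cell_radius[1] >= self.image_size:
            raise ConfigurationError("cells must fit inside the frame "
                                     "(2 * max radius < image_size)")
        if self.contrast <= 3 * self.background_noise_sigma:
            raise ConfigurationError("contrast must exceed 3x background noise "
                                     "so cells are detectable by construction")

    @property
    def background_level(self) -> float:
        return 220.0 if self.modality == "lightfield" else 25.0

    def cell_level(self, class_id: int) -> float:
        """Mean foreground intensity for a class; gap from background >= contrast."""
        offset = self.contrast + 15.0 + 12.0 * class_id
        if self.modality == "lightfield":
            return max(self.background_level - offset, 2.0)
        return min(self.background_level + offset, 253.0)


@dataclass
class GroundTruthInstance:
    mask: np.ndarray   # image-sized boolean array
    bbox: np.ndarray   # [x_min, y_min, x_max, y_max], half-open, = tight extent
    class_id: int


def tight_bbox(mask: np.ndarray) -> np.ndarray:
    """Tight half-open box over a boolean mask's foreground."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=float)


def make_background(config: FixtureConfig, rng: np.random.Generator) -> ImageSample:
    """Smooth low-frequency shading plus Gaussian pixel noise, no annotations."""
    n = config.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float) / n
    shade = np.zeros((n, n))
    for _ in range(2):
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        shade += np.cos(2 * np.pi * (fx * xx + fy * yy) + phase)
    shade *= config.shading_amplitude / 2.0
    base = config.background_level + shade
    img = base[..., None] + rng.normal(0, config.background_noise_sigma, size=(n, n, 3)) \
        if config.background_noise_sigma > 0 else np.repeat(base[..., None], 3, axis=2)
    return ImageSample(image=np.clip(np.rint(img), 0, 255).astype(np.uint8))


def _render_local_cell(config: FixtureConfig, class_id: int,
                       rng: np.random.Generator, angle: float | None):
    """Render one blob in local coordinates; returns (rgb, mask)."""
    a = rng.uniform(*config.cell_radius)
    ecc = rng.uniform(*config.cell_eccentricity)
    b = a * np.sqrt(1.0 - ecc**2)
    theta = rng.uniform(0, 2 * np.pi) if angle is None else float(angle)
    amp = config.boundary_irregularity
    freq = int(rng.integers(3, 7))
    phase = rng.uniform(0, 2 * np.pi)

    half = int(np.ceil(a * (1 + amp))) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    xr = xx * ct + yy * st
    yr = -xx * st + yy * ct
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    ang = np.arctan2(yr / b, xr / a)
    mask = rho <= 1.0 + amp * np.sin(freq * ang + phase)

    level = config.cell_level(class_id)
    # class-dependent texture: deterministic in class_id, not in the rng stream
    tex_freq = 0.35 + 0.25 * class_id
    tex = 8.0 * np.sin(tex_freq * xx + 0.7 * class_id) * np.cos(tex_freq * yy - 0.3 * class_id)
    rgb = np.clip(level + tex, 0, 255)
    rgb = np.repeat(rgb[..., None], 3, axis=2)
    # strong class-specific stain tint, emulating dye-separable cell types
    # (class 0 magenta-ish like a nucleus stain, class 1 cyan-ish, ...)
    tints = [(1.0, 0.55, 0.8), (0.55, 0.8, 1.0), (0.7, 1.0, 0.55), (1.0, 0.9, 0.5)]
    tint = np.array(tints[class_id % len(tints)])
    rgb = np.clip(rgb * tint, 0, 255).astype(np.uint8)
    return rgb, mask


def make_cell(config: FixtureConfig, class_id: int, rng: np.random.Generator,
              center: tuple | None = None, angle: float | None = None):
    """Render one cell; returns (CellPatch, GroundTruthInstance).

    The ground-truth mask is image-sized with the cell placed at `center`
    (random, fully inside the frame, when None); the patch is the tight crop.
    """
    if class_id >= config.n_classes:
        raise ConfigurationError(f"class_id {class_id} >= n_classes {config.n_classes}")
    rgb, mask = _render_local_cell(config, class_id, rng, angle)
    h = mask.shape[0]
    half = h // 2
    n = config.image_size
    if center is None:
        cy = int(rng.integers(half, n - half))
        cx = int(rng.integers(half, n - half))
    else:
        cx, cy = center
    full = np.zeros((n, n), dtype=bool)
    y0, x0 = cy - half, cx - half
    ys0, xs0 = max(0, -y0), max(0, -x0)
    ye = min(h, n - y0)
    xe = min(h, n - x0)
    full[y0 + ys0:y0 + ye, x0 + xs0:x0 + xe] = mask[ys0:ye, xs0:xe]
    bbox = tight_bbox(full)
    x_min, y_min, x_max, y_max = bbox.astype(int)
    lm = full[y_min:y_max, x_min:x_max]
    # carve the rgb crop out of the local render, aligned to the full-frame bbox
    ly0, lx0 = y_min - y0, x_min - x0
    crop_rgb = rgb[ly0:ly0 + lm.shape[0], lx0:lx0 + lm.shape[1]].copy()
    patch = CellPatch(rgb=crop_rgb, alpha=lm.astype(np.float64), class_id=class_id,
                      provenance=f"fixture:{x_min},{y_min},{x_max},{y_max}")
    return patch, GroundTruthInstance(mask=full, bbox=bbox, class_id=class_id)


def _bbox_iou(a: np.ndarray, b: np.ndarray) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    area = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / area


def make_detection_dataset(config: FixtureConfig, class_names: list | None = None,
                           return_instances: bool = False):
    """n_images samples with zero-IoU cell placement and pixel-exact boxes.

    With `return_instances=True` also returns, per image, the list of
    :class:`GroundTruthInstance` (including pixel masks) for oracle tests.
    """
    rng = np.random.default_rng(config.seed)
    class_names = class_names or default_class_names(config.n_classes)
    samples = []
    instances = []
    for image_id in range(config.n_images):
        bg = make_background(config, rng)
        img = bg.image.astype(np.int16)
        k = int(rng.integers(config.cells_per_image[0], config.cells_per_image[1] + 1))
        annotations, boxes, gts = [], [], []
        for _ in range(k):
            class_id = int(rng.integers(config.n_classes))
            placed = False
            for _attempt in range(100):
                patch, gt = make_cell(config, class_id, rng)
                if all(_bbox_iou(gt.bbox, b) == 0.0 for b in boxes):
                    placed = True
                    break
            if not placed:
                raise CapacityError(
                    f"could not place cell {len(boxes) + 1} of {k} in image "
                    f"{image_id} within 100 attempts")
            img[gt.mask] = _place_pixels(patch, gt)
            boxes.append(gt.bbox)
            gts.append(gt)
            annotations.append(Annotation(bbox=gt.bbox, class_id=class_id))
        samples.append(ImageSample(image=img.astype(np.uint8), annotations=annotations,
                                   image_id=image_id, provenance="real"))
        instances.append(gts)
    dataset = DetectionDataset(samples=samples, class_names=class_names)
    return (dataset, instances) if return_instances else dataset


def _place_pixels(patch: CellPatch, gt: GroundTruthInstance) -> np.ndarray:
    """Foreground pixel values of `patch` in mask order within gt.bbox."""
    x0, y0, x1, y1 = gt.bbox.astype(int)
    local = gt.mask[y0:y1, x0:x1]
    return patch.rgb[local]


def make_patch_bank(config: FixtureConfig, n_patches: int = 40) -> list:
    """Class-balanced labeled cutouts with no image-level boxes."""
    rng = np.random.default_rng(config.seed)
    bank = []
    for i in range(n_patches):
        class_id = i % config.n_classes
        patch, _ = make_cell(config, class_id, rng)
        bank.append(patch)
    bank.sort(key=lambda p: p.class_id)
    return bank
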