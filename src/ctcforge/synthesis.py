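"""Copy-paste image synthesis: cutout extraction, augmentation, pasting, noise.

Turns classification-only cell patches into detection training data: cell
cutouts (with per-pixel opacity from their segmentation masks) are color
jittered, rotated and scaled, alpha-composited onto unoccupied background
regions, and the paste location yields the bounding-box annotation. Gaussian
noise is added last to regularize the synthetic distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import Annotation, CellPatch, DetectionDataset, ImageSample
from .errors import (CapacityError, ConfigurationError, EmptyMaskError,
                     PlacementError)
from .fixtures import tight_bbox

__all__ = ["AugmentParams", "NoiseSpec", "PastePolicy", "SynthesisConfig",
           "extract_cutout", "augment_patch", "paste_patch",
           "add_gaussian_noise", "synthesize_dataset"]


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the jitter -> rotate -> scale augmentation composition."""

    scale: tuple = (0.7, 1.3)       # multiplicative size factor, within (0, 8]
    rotation: tuple = (0.0, 360.0)  # degrees
    jitter: tuple = (0.9, 1.1)      # per-channel multiplicative, within [0.5, 2]

    def __post_init__(self):
        if not (0 < self.scale[0] <= self.scale[1] <= 8):
            raise ConfigurationError("scale range must lie within (0, 8]")
        if not (0.5 <= self.jitter[0] <= self.jitter[1] <= 2):
            raise ConfigurationError("jitter range must lie within [0.5, 2]")

    @property
    def is_identity(self) -> bool:
        return (self.scale == (1, 1) and self.jitter == (1, 1)
                and self.rotation[0] == self.rotation[1] == 0)


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float = 5.0  # std of additive Gaussian noise, 8-bit units

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


@dataclass(frozen=True)
class PastePolicy:
    max_overlap_iou: float = 0.0
    max_attempts: int = 100


@dataclass(frozen=True)
class SynthesisConfig:
    n_images: int = 10
    cells_per_image: tuple = (1, 4)
    augment: AugmentParams = field(default_factory=AugmentParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    policy: PastePolicy = field(default_factory=PastePolicy)
    seed: int = 0


def extract_cutout(image, mask: np.ndarray) -> CellPatch:
    """Crop the mask's tight bbox; alpha is the mask restricted to the crop."""
    img = image.image if isinstance(image, ImageSample) else image
    image_id = image.image_id if isinstance(image, ImageSample) else 0
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot extract a cutout from an empty mask")
    if mask.shape != img.shape[:2]:
        raise ValueError("mask must be image-shaped")
    x0, y0, x1, y1 = tight_bbox(mask).astype(int)
    return CellPatch(
        rgb=img[y0:y1, x0:x1].copy(),
        alpha=mask[y0:y1, x0:x1].astype(np.float64),
        class_id=-1,
        provenance=f"{image_id}:{x0},{y0},{x1},{y1}",
    )


def _crop_to_support(rgb: np.ndarray, alpha: np.ndarray):
    """Tight-crop to the opaque support (alpha > 0.5)."""
    support = alpha > 0.5
    if not support.any():
        raise EmptyMaskError("augmentation left no opaque support")
    x0, y0, x1, y1 = tight_bbox(support).astype(int)
    return rgb[y0:y1, x0:x1], alpha[y0:y1, x0:x1]


def augment_patch(patch: CellPatch, params: AugmentParams,
                  rng: np.random.Generator) -> CellPatch:
    """Color jitter, then rotation (expanded canvas), then scaling.

    Exact multiples of 90 degrees are applied as index permutations so no
    interpolation artifacts arise; other angles use bilinear resampling for
    both color and opacity. The result is tight-cropped to its opaque
    support (alpha > 0.5).
    """
    if params.is_identity:
        return CellPatch(rgb=patch.rgb.copy(), alpha=patch.alpha.copy(),
                         class_id=patch.class_id, provenance=patch.provenance)
    rgb = patch.rgb.astype(np.float64)
    alpha = patch.alpha.astype(np.float64)

    factors = rng.uniform(params.jitter[0], params.jitter[1], size=3)
    rgb = np.clip(rgb * factors, 0, 255)

    angle = float(rng.uniform(params.rotation[0], params.rotation[1]))
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        if k:
            rgb = np.rot90(rgb, k=k, axes=(0, 1))
            alpha = np.rot90(alpha, k=k)
    elif angle != 0:
        rgb = ndimage.rotate(rgb, angle, axes=(1, 0), reshape=True, order=1,
                             mode="constant", cval=0.0)
        alpha = ndimage.rotate(alpha, angle, axes=(1, 0), reshape=True, order=1,
                               mode="constant", cval=0.0)

    scale = float(rng.uniform(params.scale[0], params.scale[1]))
    if scale != 1.0:
        rgb = ndimage.zoom(rgb, (scale, scale, 1), order=1)
        alpha = ndimage.zoom(alpha, (scale, scale), order=1)

    alpha = np.clip(alpha, 0.0, 1.0)
    rgb, alpha = _crop_to_support(rgb, alpha)
    return CellPatch(rgb=np.clip(np.rint(rgb), 0, 255).astype(np.uint8),
                     alpha=np.ascontiguousarray(alpha), class_id=patch.class_id,
                     provenance=patch.provenance)


def _iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua


def paste_patch(background: ImageSample, patch: CellPatch, occupied: list,
                policy: PastePolicy = PastePolicy(),
                rng: np.random.Generator | None = None):
    """Alpha-composite `patch` at a uniform position with bounded box overlap.

    Returns the composited :class:`ImageSample` (the input is not mutated)
    and the pasted patch's tight opaque-extent bbox. The caller is expected
    to append the bbox to `occupied` for subsequent pastes.
    """
    rng = rng or np.random.default_rng()
    img = background.image
    h, w = img.shape[:2]
    support = patch.alpha > 0.5
    sx0, sy0, sx1, sy1 = tight_bbox(support).astype(int)
    ph, pw = patch.alpha.shape
    if ph > h or pw > w:
        raise PlacementError("patch larger than background")
    for _ in range(policy.max_attempts):
        x = int(rng.integers(0, w - pw + 1))
        y = int(rng.integers(0, h - ph + 1))
        bbox = np.array([x + sx0, y + sy0, x + sx1, y + sy1], dtype=float)
        if all(_iou(bbox, b) <= policy.max_overlap_iou + 1e-12 for b in occupied):
            out = img.astype(np.float64).copy()
            a = patch.alpha[..., None]
            region = out[y:y + ph, x:x + pw]
            out[y:y + ph, x:x + pw] = region * (1 - a) + patch.rgb.astype(np.float64) * a
            sample = ImageSample(image=np.clip(np.rint(out), 0, 255).astype(np.uint8),
                                 annotations=list(background.annotations),
                                 image_id=background.image_id,
                                 provenance=background.provenance)
            return sample, bbox
    raise PlacementError(
        f"no valid position after {policy.max_attempts} attempts "
        f"(occupied={len(occupied)}, max_overlap_iou={policy.max_overlap_iou})")


def add_gaussian_noise(image: ImageSample, spec: NoiseSpec,
                       rng: np.random.Generator) -> ImageSample:
    """Add i.i.d. zero-mean Gaussian noise per channel, clipped to [0, 255]."""
    if spec.sigma == 0:
        return ImageSample(image=image.image.copy(), annotations=list(image.annotations),
                           image_id=image.image_id, provenance=image.provenance)
    noisy = image.image.astype(np.float64) + rng.normal(0, spec.sigma, image.image.shape)
    return ImageSample(image=np.clip(np.rint(noisy), 0, 255).astype(np.uint8),
                       annotations=list(image.annotations), image_id=image.image_id,
                       provenance=image.provenance)


def synthesize_dataset(patch_bank: list, backgrounds: list,
                       config: SynthesisConfig,
                       class_names: list | None = None) -> DetectionDataset:
    """Build a synthetic detection dataset by copy-paste onto backgrounds.

    Per image: sample a background, sample k patches with replacement,
    augment each, paste under the overlap policy (failed placements are
    skipped), then add Gaussian noise. Emitted annotations correspond
    one-to-one to successful pastes; pre-existing background boxes only
    seed the occupied list so pastes avoid real cells.
    """
    if not patch_bank or not backgrounds:
        raise ValueError("patch bank and backgrounds must be nonempty")
    rng = np.random.default_rng(config.seed)
    if class_names is None:
        n_classes = max(p.class_id for p in patch_bank) + 1
        from .fixtures import default_class_names
        class_names = default_class_names(n_classes)
    samples = []
    for image_id in range(config.n_images):
        bg = backgrounds[int(rng.integers(len(backgrounds)))]
        current = ImageSample(image=bg.image.copy(), annotations=[],
                              image_id=image_id, provenance="synthetic")
        occupied = [a.bbox.copy() for a in bg.annotations]
        k = int(rng.integers(config.cells_per_image[0], config.cells_per_image[1] + 1))
        annotations = []
        for _ in range(k):
            patch = patch_bank[int(rng.integers(len(patch_bank)))]
            aug = augment_patch(patch, config.augment, rng)
            try:
                current, bbox = paste_patch(current, aug, occupied,
                                            config.policy, rng)
            except PlacementError:
                continue
            occupied.append(bbox)
            annotations.append(Annotation(bbox=bbox, class_id=aug.class_id))
        if not annotations:
            raise CapacityError(f"zero successful pastes for image {image_id}")
        current.annotations = annotations
        samples.append(add_gaussian_noise(current, config.noise, rng))
    return DetectionDataset(samples=samples, class_names=class_names)
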