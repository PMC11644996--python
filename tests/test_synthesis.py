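"""Copy-paste synthesis: cutouts, augmentation, pasting, noise, invariants."""

import numpy as np
import pytest

from ctcforge.data import CellPatch, ImageSample
from ctcforge.errors import (CapacityError, ConfigurationError, EmptyMaskError,
                             PlacementError)
from ctcforge.fixtures import FixtureConfig, make_background, make_patch_bank
from ctcforge.segmentation import mask_to_bbox
from ctcforge.synthesis import (AugmentParams, NoiseSpec, PastePolicy,
                                SynthesisConfig, add_gaussian_noise,
                                augment_patch, extract_cutout, paste_patch,
                                synthesize_dataset)

IDENTITY = AugmentParams(scale=(1, 1), rotation=(0, 0), jitter=(1, 1))


def _image(size=64, value=100):
    return np.full((size, size, 3), value, dtype=np.uint8)


def _square_patch(side=10, value=200, class_id=0):
    return CellPatch(rgb=np.full((side, side, 3), value, dtype=np.uint8),
                     alpha=np.ones((side, side)), class_id=class_id)


class TestExtractCutout:
    def test_identity_mask(self):
        img = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
        patch = extract_cutout(img, np.ones((4, 4), bool))
        np.testing.assert_array_equal(patch.rgb, img)
        assert (patch.alpha == 1).all()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_cutout(_image(), np.zeros((64, 64), bool))

    def test_half_plane_mask_alpha_matches_crop(self):
        mask = np.zeros((64, 64), bool)
        mask[:, 20:] = True
        patch = extract_cutout(_image(), mask)
        np.testing.assert_array_equal(patch.alpha, mask[:, 20:].astype(float))


class TestAugmentPatch:
    def test_identity_params_exact(self, rng):
        patch = _square_patch()
        out = augment_patch(patch, IDENTITY, rng)
        np.testing.assert_array_equal(out.rgb, patch.rgb)
        np.testing.assert_array_equal(out.alpha, patch.alpha)

    def test_exact_90_degree_rotation_is_index_permutation(self, rng):
        cfg = FixtureConfig()
        patch = make_patch_bank(cfg, n_patches=1)[0]
        params = AugmentParams(scale=(1, 1), rotation=(90, 90), jitter=(1, 1))
        out = augment_patch(patch, params, rng)
        np.testing.assert_array_equal(out.alpha, np.rot90(patch.alpha))

    def test_scale_doubles_dimensions_and_area(self, rng):
        patch = _square_patch(10)
        params = AugmentParams(scale=(2, 2), rotation=(0, 0), jitter=(1, 1))
        out = augment_patch(patch, params, rng)
        assert out.alpha.shape == (20, 20)
        area_ratio = (out.alpha > 0.5).sum() / (patch.alpha > 0.5).sum()
        assert abs(area_ratio - 4.0) / 4.0 < 0.1

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            AugmentParams(scale=(0, 2))
        with pytest.raises(ConfigurationError):
            AugmentParams(jitter=(0.1, 1))


class TestPastePatch:
    def test_unconstrained_placement_bbox_is_opaque_extent(self, rng):
        bg = ImageSample(image=_image(64))
        patch = _square_patch(10)
        out, bbox = paste_patch(bg, patch, occupied=[], rng=rng)
        assert 0 <= bbox[0] < bbox[2] <= 64 and 0 <= bbox[1] < bbox[3] <= 64
        assert bbox[2] - bbox[0] == 10 and bbox[3] - bbox[1] == 10

    def test_fully_occupied_raises(self, rng):
        bg = ImageSample(image=_image(64))
        patch = _square_patch(10)
        with pytest.raises(PlacementError):
            paste_patch(bg, patch, occupied=[np.array([0, 0, 64, 64])],
                        policy=PastePolicy(max_overlap_iou=0.0, max_attempts=30),
                        rng=rng)

    def test_opaque_patch_pixel_exact(self, rng):
        bg = ImageSample(image=_image(64, value=50))
        patch = _square_patch(8, value=220)
        out, bbox = paste_patch(bg, patch, occupied=[], rng=rng)
        x0, y0, x1, y1 = bbox.astype(int)
        assert (out.image[y0:y1, x0:x1] == 220).all()
        outside = out.image.copy()
        outside[y0:y1, x0:x1] = 50
        assert (outside == 50).all()

    def test_input_background_not_mutated(self, rng):
        bg = ImageSample(image=_image(64, value=50))
        before = bg.image.copy()
        paste_patch(bg, _square_patch(8), occupied=[], rng=rng)
        np.testing.assert_array_equal(bg.image, before)


class TestNoise:
    def test_sigma_zero_identity(self, rng):
        img = ImageSample(image=_image(64))
        out = add_gaussian_noise(img, NoiseSpec(sigma=0.0), rng)
        np.testing.assert_array_equal(out.image, img.image)

    def test_sample_std_matches_sigma(self):
        img = ImageSample(image=np.full((256, 256, 3), 128, dtype=np.uint8))
        out = add_gaussian_noise(img, NoiseSpec(sigma=10.0),
                                 np.random.default_rng(0))
        resid = out.image.astype(float) - 128.0
        assert abs(resid.std() - 10.0) / 10.0 < 0.05

    def test_same_seed_bit_identical(self):
        img = ImageSample(image=_image(64))
        a = add_gaussian_noise(img, NoiseSpec(5.0), np.random.default_rng(9))
        b = add_gaussian_noise(img, NoiseSpec(5.0), np.random.default_rng(9))
        np.testing.assert_array_equal(a.image, b.image)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseSpec(sigma=-1.0)


@pytest.fixture(scope="module")
def synth_inputs():
    cfg = FixtureConfig(image_size=96, cell_radius=(5.0, 9.0), seed=17)
    bank = make_patch_bank(cfg, n_patches=12)
    rng = np.random.default_rng(17)
    backgrounds = [make_background(cfg, rng) for _ in range(3)]
    return bank, backgrounds


class TestSynthesizeDataset:
    def test_count_conservation_with_permissive_policy(self, synth_inputs):
        bank, bgs = synth_inputs
        cfg = SynthesisConfig(n_images=10, cells_per_image=(3, 3),
                              policy=PastePolicy(max_overlap_iou=1.0),
                              noise=NoiseSpec(0.0), seed=1)
        ds = synthesize_dataset(bank, bgs, cfg)
        assert ds.n_annotations == 30

    def test_determinism(self, synth_inputs):
        bank, bgs = synth_inputs
        cfg = SynthesisConfig(n_images=5, seed=3)
        a = synthesize_dataset(bank, bgs, cfg)
        b = synthesize_dataset(bank, bgs, cfg)
        assert a.canonical_json() == b.canonical_json()
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(sa.image, sb.image)

    def test_no_augment_no_noise_pixels_match_source_patch(self, synth_inputs):
        _, bgs = synth_inputs
        patch = _square_patch(9, value=201, class_id=1)
        cfg = SynthesisConfig(n_images=3, cells_per_image=(1, 1),
                              augment=IDENTITY, noise=NoiseSpec(0.0), seed=5)
        ds = synthesize_dataset([patch], bgs, cfg, class_names=["a", "b"])
        for s in ds.samples:
            (ann,) = s.annotations
            x0, y0, x1, y1 = ann.bbox.astype(int)
            np.testing.assert_array_equal(s.image[y0:y1, x0:x1], patch.rgb)

    def test_provenance_marked_synthetic(self, synth_inputs):
        bank, bgs = synth_inputs
        ds = synthesize_dataset(bank, bgs, SynthesisConfig(n_images=2, seed=2))
        assert all(s.provenance == "synthetic" for s in ds.samples)


class TestSynthesisInvariants:
    """Box/pixel consistency and the overlap policy on a 50-image batch."""

    @pytest.fixture(scope="class")
    def synthetic_50(self):
        cfg = FixtureConfig(image_size=96, cell_radius=(5.0, 9.0), seed=23)
        bank = make_patch_bank(cfg, n_patches=20)
        rng = np.random.default_rng(23)
        bgs = [make_background(cfg, rng) for _ in range(5)]
        sc = SynthesisConfig(n_images=50, cells_per_image=(1, 3), seed=29,
                             noise=NoiseSpec(sigma=4.0))
        return bank, bgs, sc, synthesize_dataset(bank, bgs, sc)

    def test_boxes_within_bounds(self, synthetic_50):
        *_, ds = synthetic_50
        for s in ds.samples:
            for a in s.annotations:
                x0, y0, x1, y1 = a.bbox
                assert 0 <= x0 < x1 <= s.width and 0 <= y0 < y1 <= s.height

    def test_pairwise_iou_respects_policy(self, synthetic_50):
        from ctcforge.evaluation import iou
        bank, bgs, sc, ds = synthetic_50
        for s in ds.samples:
            boxes = [a.bbox for a in s.annotations]
            for i in range(len(boxes)):
                for j in range(i + 1, len(boxes)):
                    assert iou(boxes[i], boxes[j]) <= sc.policy.max_overlap_iou + 1e-12

    def test_label_conservation(self, synthetic_50):
        bank, bgs, sc, ds = synthetic_50
        # replay the sampling to recover which classes were pasted
        assert set(a.class_id for s in ds.samples for a in s.annotations) \
            <= set(p.class_id for p in bank)

    def test_annotation_bbox_equals_opaque_support(self, synthetic_50):
        """Re-run the paste pipeline recording alpha supports and check that
        each stored bbox equals the tight opaque extent placed there."""
        bank, bgs, sc, ds = synthetic_50
        rng = np.random.default_rng(sc.seed)
        for image_id in range(sc.n_images):
            bg = bgs[int(rng.integers(len(bgs)))]
            occupied = [a.bbox.copy() for a in bg.annotations]
            k = int(rng.integers(sc.cells_per_image[0], sc.cells_per_image[1] + 1))
            placed = []
            current = ImageSample(image=bg.image.copy(), image_id=image_id)
            for _ in range(k):
                patch = bank[int(rng.integers(len(bank)))]
                aug = augment_patch(patch, sc.augment, rng)
                try:
                    current, bbox = paste_patch(current, aug, occupied,
                                                sc.policy, rng)
                except PlacementError:
                    continue
                occupied.append(bbox)
                support = aug.alpha > 0.5
                sup_box = mask_to_bbox(support)
                assert sup_box[0] == 0 and sup_box[1] == 0  # tight-cropped patch
                placed.append((bbox, support))
            stored = ds.samples[image_id].annotations
            assert len(stored) == len(placed)
            for ann, (bbox, support) in zip(stored, placed):
                np.testing.assert_array_equal(ann.bbox, bbox)
                w, h = support.shape[1], support.shape[0]
                assert (ann.bbox[2] - ann.bbox[0], ann.bbox[3] - ann.bbox[1]) == (w, h)
            _ = add_gaussian_noise(current, sc.noise, rng)  # keep rng aligned
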