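"""Detection framework: shape contracts, structural equivalences, complexity."""

from dataclasses import replace

import numpy as np
import pytest

from ctcforge._tensor import Tensor, conv2d
from ctcforge.errors import ShapeError
from ctcforge.model import (CTCDetectionModel, ModelConfig, PAPER_BASE,
                            TINY_TEST, ScaleAdapter, count_flops,
                            count_parameters, nms)
from ctcforge.nn import Conv2d


@pytest.fixture(scope="module")
def tiny_model():
    return CTCDetectionModel(TINY_TEST, seed=0)


def _input(n=1, side=64, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, 3, side, side)).astype(np.float32)


class TestPatchEmbed:
    def test_token_map_shape(self, tiny_model):
        tok = tiny_model.patch_embed(Tensor(_input(side=64)))
        assert tok.shape == (1, 16, 16, TINY_TEST.embed_dim)

    def test_indivisible_side_raises_with_padding_hint(self, tiny_model):
        with pytest.raises(ShapeError, match="divisible"):
            tiny_model.forward(_input(side=60))

    def test_zero_pos_embed_equals_projection(self):
        m = CTCDetectionModel(TINY_TEST, seed=1)
        m.patch_embed.pos.data[:] = 0.0
        x = Tensor(_input(side=64))
        tok = m.patch_embed(x)
        proj = m.patch_embed.proj(x).transpose(0, 2, 3, 1)
        np.testing.assert_array_equal(tok.data, proj.data)

    def test_locality_of_nonoverlapping_patches(self, tiny_model):
        a = _input(side=64, seed=3)
        b = a.copy()
        b[:, :, 8:12, 16:20] += 1.0  # exactly one 4x4 patch
        ta = tiny_model.patch_embed(Tensor(a)).data
        tb = tiny_model.patch_embed(Tensor(b)).data
        diff = np.abs(ta - tb).sum(axis=-1)[0]
        changed = np.argwhere(diff > 1e-6)
        assert changed.tolist() == [[2, 4]]


class TestBackbone:
    def test_stage_shapes(self, tiny_model):
        tok = tiny_model.patch_embed(Tensor(_input(side=64)))
        feats = tiny_model.backbone(tok)
        shapes = [f.shape[1:] for f in feats]
        assert shapes == [(32, 16, 16), (64, 8, 8), (128, 4, 4), (256, 2, 2)]

    def test_deterministic_forward(self, tiny_model):
        x = _input(side=64, seed=5)
        a = tiny_model.forward(x)
        b = tiny_model.forward(x)
        for (ca, _), (cb, _) in zip(a, b):
            np.testing.assert_array_equal(ca.data, cb.data)

    def test_window_size_affects_attention(self):
        """Same shared weights, different window partition -> different output."""
        m4 = CTCDetectionModel(replace(TINY_TEST, window_size=4), seed=2)
        m2 = CTCDetectionModel(replace(TINY_TEST, window_size=2), seed=2)
        # share every weight except the (window-sized) relative bias tables,
        # which are zeroed in both models
        state = m4.state_dict()
        for name, p in m2.named_parameters():
            if "rel_bias" in name:
                p.data[:] = 0.0
            else:
                p.data = state[name].copy()
        for name, p in m4.named_parameters():
            if "rel_bias" in name:
                p.data[:] = 0.0
        x = _input(side=64, seed=7)
        ta = m4.patch_embed(Tensor(x))
        tb = m2.patch_embed(Tensor(x))
        fa = m4.backbone(ta)[0].data
        fb = m2.backbone(tb)[0].data
        assert np.abs(fa - fb).max() > 1e-4


class TestScaleAdapter:
    def test_shape_contract(self, tiny_model):
        x = _input(side=64)
        feats = tiny_model.backbone(tiny_model.patch_embed(Tensor(x)))
        pyr = tiny_model.scale_adapter(feats)
        c = TINY_TEST.pyramid_channels
        assert [p.shape[1:] for p in pyr] == [(c, 16, 16), (c, 8, 8),
                                              (c, 4, 4), (c, 2, 2)]

    def test_two_level_topdown_hand_computation(self):
        """Identity laterals + identity output convs: finest level equals its
        lateral plus the 2x-upsampled coarser lateral."""
        rng = np.random.default_rng(0)
        fpn = ScaleAdapter((3, 3), channels=3, rng=rng)
        for lat in fpn.laterals:
            lat.weight.data = np.eye(3, dtype=np.float32)[:, :, None, None]
            lat.bias.data[:] = 0.0
        for out in fpn.outputs:
            out.weight.data[:] = 0.0
            out.weight.data[np.arange(3), np.arange(3), 1, 1] = 1.0
            out.bias.data[:] = 0.0
        fine = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        coarse = rng.normal(size=(1, 3, 2, 2)).astype(np.float32)
        levels = fpn([Tensor(fine), Tensor(coarse)])
        expect = fine + coarse.repeat(2, axis=2).repeat(2, axis=3)
        np.testing.assert_allclose(levels[0].data, expect, rtol=1e-6)
        np.testing.assert_allclose(levels[1].data, coarse, rtol=1e-6)

    def test_zero_weights_zero_pyramid(self):
        rng = np.random.default_rng(0)
        fpn = ScaleAdapter((4, 8), channels=4, rng=rng)
        for conv in fpn.laterals + fpn.outputs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        outs = fpn([Tensor(np.ones((1, 4, 4, 4), np.float32)),
                    Tensor(np.ones((1, 8, 2, 2), np.float32))])
        for o in outs:
            assert np.abs(o.data).max() == 0.0


class TestShapeAdapter:
    def test_zero_offsets_equal_standard_conv(self, tiny_model, rng):
        dc = tiny_model.shape_adapter.convs[0]
        dc.offset_conv.weight.data[:] = 0.0
        dc.offset_conv.bias.data[:] = 0.0
        c = dc.channels
        x = Tensor(rng.normal(size=(2, c, 8, 8)).astype(np.float32))
        out = dc(x)
        ref = conv2d(x, Tensor(dc.equivalent_standard_kernel()),
                     dc.weight_conv.bias, padding=1)
        np.testing.assert_allclose(out.data, ref.data, rtol=1e-5, atol=1e-5)

    def test_constant_half_pixel_offset_closed_form(self):
        """Center tap with (+0.5, +0.5) offsets averages the 2x2 neighborhood."""
        from ctcforge._tensor import deform_sample
        x = np.zeros((1, 1, 6, 6), dtype=np.float64)
        x[0, 0, 2, 3] = 1.0
        off = np.full((1, 18, 6, 6), 0.5)
        taps = deform_sample(Tensor(x), Tensor(off)).data.reshape(9, 1, 6, 6)
        center = taps[4, 0]
        expect = np.zeros((6, 6))
        # bilinear at (i+0.5, j+0.5): the delta at (2,3) contributes 0.25 to
        # each sampling location whose 2x2 support contains it
        for i, j in [(1, 2), (1, 3), (2, 2), (2, 3)]:
            expect[i, j] = 0.25
        np.testing.assert_allclose(center, expect, atol=1e-12)

    def test_shape_preserved(self, tiny_model, rng):
        c = TINY_TEST.pyramid_channels
        x = Tensor(rng.normal(size=(1, c, 8, 8)).astype(np.float32))
        out = tiny_model.shape_adapter.convs[1](x)
        assert out.shape == (1, c, 8, 8)


class TestDetectionHead:
    def test_softmax_rows_sum_to_one(self, tiny_model):
        out = tiny_model.forward(_input(side=64))
        for cls_logits, _ in out:
            probs = cls_logits.softmax(axis=1).data
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_location_count_on_64_input(self, tiny_model):
        out = tiny_model.forward(_input(side=64))
        total = sum(c.shape[2] * c.shape[3] for c, _ in out)
        assert total == 16**2 + 8**2 + 4**2 + 2**2 == 340

    def test_zero_box_weights_decode_to_prior_boxes(self):
        m = CTCDetectionModel(TINY_TEST, seed=3)
        m.head.box_proj.weight.data[:] = 0.0
        m.head.box_proj.bias.data[:] = 0.0
        out = m.forward(_input(side=64))
        decoded = m.decode(out, (64, 64))
        for (probs, boxes), s in zip(decoded, TINY_TEST.strides):
            hl = boxes.shape[2]
            for i in (0, hl - 1):
                for j in (0, hl - 1):
                    cx, cy = (j + 0.5) * s, (i + 0.5) * s
                    expect = [max(cx - s, 0), max(cy - s, 0),
                              min(cx + s, 64), min(cy + s, 64)]
                    np.testing.assert_allclose(boxes[0, :, i, j], expect,
                                               rtol=1e-5)

    def test_class_channel_permutation(self, tiny_model):
        """Permuting class output channels permutes scores identically."""
        m = CTCDetectionModel(TINY_TEST, seed=4)
        x = _input(side=64)
        base = m.forward(x)[0][0].softmax(axis=1).data
        perm = [1, 0, 2]  # swap the two foreground classes, keep background
        m.head.cls_proj.weight.data = m.head.cls_proj.weight.data[perm]
        m.head.cls_proj.bias.data = m.head.cls_proj.bias.data[perm]
        swapped = m.forward(x)[0][0].softmax(axis=1).data
        np.testing.assert_allclose(swapped, base[:, perm], atol=1e-6)


class TestGradientFlow:
    def test_every_adapter_and_head_parameter_gets_gradient(self):
        m = CTCDetectionModel(TINY_TEST, seed=0)
        out = m.forward(_input(n=2, side=64, seed=9))
        loss = None
        for c, b in out:
            t = (c * c).sum() + (b * b).sum()
            loss = t if loss is None else loss + t
        loss.backward()
        dead = [name for name, p in m.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []


class TestComplexity:
    def test_lone_conv_parameter_count(self):
        conv = Conv2d(2, 4, 3, np.random.default_rng(0))
        assert conv.weight.data.size + conv.bias.data.size == 76

    def test_count_deterministic(self, tiny_model):
        assert count_parameters(tiny_model) == count_parameters(tiny_model)

    def test_flops_scale_quadratically_with_side(self):
        a = count_flops(TINY_TEST, 64)
        b = count_flops(TINY_TEST, 128)
        assert 3.0 < b / a < 4.5  # dense ops scale ~4x, attention a bit more


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, tiny_model):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = CTCDetectionModel.load(path)
        x = _input(side=64, seed=11)
        a = tiny_model.forward(x)
        b = loaded.forward(x)
        for (ca, ba), (cb, bb) in zip(a, b):
            np.testing.assert_array_equal(ca.data, cb.data)
            np.testing.assert_array_equal(ba.data, bb.data)


class TestNms:
    def test_suppresses_overlapping_same_class(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40]],
                         dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), np.zeros(3, dtype=int), 0.5)
        assert keep.tolist() == [0, 2]

    def test_keeps_different_classes(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8]), np.array([0, 1]), 0.5)
        assert keep.tolist() == [0, 1]


class TestPaperBaseStructure:
    def test_stage_dims(self):
        assert PAPER_BASE.stage_dims == (128, 256, 512, 1024)
        assert PAPER_BASE.strides == (4, 8, 16, 32)
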