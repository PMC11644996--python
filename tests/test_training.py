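"""Training recipe: schedule, initialization, batch mixing, optimization."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ctcforge.fixtures import FixtureConfig, make_detection_dataset
from ctcforge.model import CTCDetectionModel, TINY_TEST
from ctcforge.training import (TrainConfig, init_adapters, lr_schedule,
                               make_mixed_batches, tiny_train_config, train)


class TestLrSchedule:
    CFG = TrainConfig(base_lr=0.001, t_max=50)

    def test_epoch_zero_is_base_lr(self):
        assert lr_schedule(0, self.CFG) == pytest.approx(0.001)

    def test_epoch_tmax_reaches_minimum(self):
        assert lr_schedule(50, self.CFG) == pytest.approx(0.0, abs=1e-12)

    def test_half_period_is_half_base(self):
        assert lr_schedule(25, self.CFG) == pytest.approx(0.0005)

    def test_closed_form_trace(self):
        for e in range(0, 100, 7):
            expect = 0.0005 * (1 + math.cos(math.pi * e / 50))
            assert lr_schedule(e, self.CFG) == pytest.approx(expect, rel=1e-12)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, self.CFG)


class TestInitAdapters:
    def test_xavier_bound_for_3x3_conv(self):
        model = CTCDetectionModel(replace(TINY_TEST, pyramid_channels=256,
                                          head_width=256), seed=0)
        init_adapters(model, rng=np.random.default_rng(0))
        w = model.scale_adapter.outputs[0].weight.data  # 3x3, 256 -> 256
        bound = math.sqrt(6.0 / (2304 + 2304))
        assert bound == pytest.approx(0.0361, abs=5e-4)
        assert np.abs(w).max() <= bound
        assert np.abs(w).max() > 0.5 * bound  # actually spread out

    def test_offset_branch_exactly_zero(self):
        model = CTCDetectionModel(TINY_TEST, seed=0)
        init_adapters(model, rng=np.random.default_rng(1))
        for conv in model.shape_adapter.convs:
            assert not conv.offset_conv.weight.data.any()
            assert not conv.offset_conv.bias.data.any()

    def test_same_seed_identical_init(self):
        a = init_adapters(CTCDetectionModel(TINY_TEST, seed=0),
                          rng=np.random.default_rng(5))
        b = init_adapters(CTCDetectionModel(TINY_TEST, seed=0),
                          rng=np.random.default_rng(5))
        for (na, pa), (_, pb) in zip(a.named_parameters(), b.named_parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            init_adapters(CTCDetectionModel(TINY_TEST), scheme="kaiming")


def _tiny_ds(n, seed, n_classes=1):
    return make_detection_dataset(
        FixtureConfig(n_images=n, image_size=64, n_classes=n_classes,
                      cell_radius=(5.0, 9.0), seed=seed))


class TestMixedBatches:
    def test_symmetric_split(self):
        real, synth = _tiny_ds(16, 1), _tiny_ds(16, 2)
        batch, n_real = next(make_mixed_batches(real, synth, 16,
                                                np.random.default_rng(0),
                                                ((64, 64),)))
        assert n_real == 8 and len(batch) == 16

    def test_one_to_three_proportion(self):
        real, synth = _tiny_ds(8, 1), _tiny_ds(24, 2)
        batch, n_real = next(make_mixed_batches(real, synth, 16,
                                                np.random.default_rng(0),
                                                ((64, 64),)))
        assert n_real == 4 and len(batch) - n_real == 12

    def test_epoch_covers_each_dataset_at_most_once(self):
        real, synth = _tiny_ds(10, 1), _tiny_ds(7, 2)
        seen_r, seen_s = [], []
        for batch, n_real in make_mixed_batches(real, synth, 4,
                                                np.random.default_rng(0),
                                                ((64, 64),)):
            seen_r.extend(s.image_id for s in batch[:n_real])
            seen_s.extend(s.image_id for s in batch[n_real:])
        assert sorted(seen_r) == list(range(10))
        assert sorted(seen_s) == list(range(7))

    def test_provenance_tags_preserved(self):
        real, synth = _tiny_ds(4, 1), _tiny_ds(4, 2)
        for s in synth.samples:
            s.provenance = "synthetic"
        batch, n_real = next(make_mixed_batches(real, synth, 4,
                                                np.random.default_rng(0),
                                                ((64, 64),)))
        assert all(s.provenance == "real" for s in batch[:n_real])
        assert all(s.provenance == "synthetic" for s in batch[n_real:])


class TestTrain:
    def test_overfit_one_fixed_batch_halves_loss(self):
        """Optimization sanity: a tiny model on 4 fixed images reaches
        <= 50% of the initial total loss within 200 iterations."""
        ds = _tiny_ds(4, seed=3)
        model = init_adapters(CTCDetectionModel(replace(TINY_TEST, n_classes=1),
                                                seed=0),
                              rng=np.random.default_rng(0))
        cfg = tiny_train_config(epochs=200, batch_size=4, seed=0,
                                multi_scale=((64, 64),), val_fraction=0.25)
        model, hist = train(model, ds, None, cfg)
        assert len(hist) == 200  # 3 train images -> one batch per epoch
        assert hist[-1]["total"] <= 0.5 * hist[0]["total"]

    def test_single_source_history_is_lc_plus_lb(self):
        ds = _tiny_ds(6, seed=4)
        model = init_adapters(CTCDetectionModel(replace(TINY_TEST, n_classes=1),
                                                seed=0),
                              rng=np.random.default_rng(0))
        cfg = tiny_train_config(epochs=2, batch_size=4, seed=0,
                                multi_scale=((64, 64),), lambda_consistency=0.0)
        _, hist = train(model, ds, None, cfg)
        for rec in hist:
            assert rec["total"] == pytest.approx(
                rec["class_term"] + rec["box_term"], rel=1e-6)

    def test_fixed_seed_reproducible_history(self):
        ds = _tiny_ds(6, seed=5)
        runs = []
        for _ in range(2):
            model = init_adapters(CTCDetectionModel(replace(TINY_TEST, n_classes=1),
                                                    seed=0),
                                  rng=np.random.default_rng(0))
            cfg = tiny_train_config(epochs=2, batch_size=4, seed=11,
                                    multi_scale=((64, 64),))
            _, hist = train(model, ds, None, cfg)
            runs.append(hist)
        assert runs[0] == runs[1]

    def test_mixed_mode_weights_constant_and_correct(self):
        real, synth = _tiny_ds(6, 6), _tiny_ds(3, 7)
        for s in synth.samples:
            s.provenance = "synthetic"
        model = init_adapters(CTCDetectionModel(replace(TINY_TEST, n_classes=1),
                                                seed=0),
                              rng=np.random.default_rng(0))
        cfg = tiny_train_config(epochs=2, batch_size=4, seed=0,
                                multi_scale=((64, 64),))
        _, hist = train(model, real, synth, cfg)
        for rec in hist:
            assert rec["w_real"] == pytest.approx(6 / 9)
            assert rec["w_synthetic"] == pytest.approx(3 / 9)

    def test_lr_trace_matches_schedule(self):
        ds = _tiny_ds(6, seed=8)
        model = init_adapters(CTCDetectionModel(replace(TINY_TEST, n_classes=1),
                                                seed=0),
                              rng=np.random.default_rng(0))
        cfg = tiny_train_config(epochs=3, batch_size=4, seed=0,
                                multi_scale=((64, 64),))
        _, hist = train(model, ds, None, cfg)
        for rec in hist:
            assert rec["lr"] == pytest.approx(lr_schedule(rec["epoch"], cfg))
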