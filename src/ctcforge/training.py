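"""Training loop: AdamW, cosine-annealed learning rate, multi-scale batches,
Xavier-initialized adapters, and the mixed real/synthetic loss.

The paper-scale recipe (base_lr 0.001, cosine period 50 over 100 epochs,
batch 16, weight decay 0.05, scales 960/1024/1280) is the default config;
`tiny_train_config` scales the recipe down for CPU-sized experiments.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from . import loss as L
from ._tensor import Tensor
from .data import DetectionDataset, ImageSample
from .evaluation import evaluate_images, map_at_50
from .model import CTCDetectionModel
from .nn import AdamW, xavier_uniform

__all__ = ["TrainConfig", "tiny_train_config", "lr_schedule", "init_adapters",
           "make_mixed_batches", "train", "predict_dataset"]


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 0.001
    t_max: int = 50               # cosine annealing period, epochs
    eta_min: float = 0.0
    epochs: int = 100
    batch_size: int = 16
    weight_decay: float = 0.05
    multi_scale: tuple = ((960, 960), (1024, 1024), (1280, 1280))
    lambda_consistency: float = 1.0
    neg_ratio: int = 3            # sampled negatives per positive location
    min_negatives: int = 8        # per level and image
    val_fraction: float = 0.2
    score_threshold: float = 0.3
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def tiny_train_config(**overrides) -> TrainConfig:
    """The CPU profile: same recipe, scaled-down sizes and epochs."""
    defaults = dict(epochs=15, batch_size=8, multi_scale=((128, 128),),
                    t_max=50)
    defaults.update(overrides)
    return TrainConfig(**defaults)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing: eta(e) = eta_min + 0.5 (eta_base - eta_min)(1 + cos(pi e/T)).

    Follows the standard CosineAnnealingLR semantics: the rate reaches
    eta_min at epoch T (= t_max) and, when training continues past T, rises
    back along the cosine (period 2T) rather than restarting.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.eta_min + 0.5 * (config.base_lr - config.eta_min) * (
        1.0 + math.cos(math.pi * epoch / config.t_max))


def init_adapters(model: CTCDetectionModel, scheme: str = "xavier",
                  rng: np.random.Generator | None = None) -> CTCDetectionModel:
    """Re-draw adapter and head weights; zero the deformable offset branch.

    Scale/shape adapter and head convolution weights are drawn
    Xavier-uniform; all biases are zeroed. The offset-prediction branch of
    each deformable convolution is zero-initialized entirely, so training
    starts from the standard-convolution limit.
    """
    if scheme != "xavier":
        raise ValueError(f"unknown init scheme {scheme!r}")
    rng = rng or np.random.default_rng(0)
    mods = [model.scale_adapter, model.shape_adapter, model.head]
    for mod in mods:
        for name, p in mod.named_parameters():
            if p.data.ndim == 4:  # conv kernels
                co, ci, kh, kw = p.data.shape
                fan_in = ci * kh * kw
                fan_out = co * kh * kw
                p.data = xavier_uniform(rng, p.data.shape, fan_in, fan_out,
                                        p.data.dtype)
            else:
                p.data = np.zeros_like(p.data)
    for conv in model.shape_adapter.convs:
        conv.offset_conv.weight.data[:] = 0.0
        if conv.offset_conv.bias is not None:
            conv.offset_conv.bias.data[:] = 0.0
    # background-prior bias: start with confident background everywhere so the
    # dense head is not flooded with false positives early in training
    model.head.cls_proj.bias.data[-1] = 4.0
    return model


def _resize_sample(sample: ImageSample, size: tuple) -> ImageSample:
    """Resize an image and its boxes to (H, W)."""
    from skimage.transform import resize

    h, w = sample.image.shape[:2]
    th, tw = size
    if (h, w) == (th, tw):
        return sample
    img = resize(sample.image, (th, tw), order=1, preserve_range=True,
                 anti_aliasing=False).astype(np.uint8)
    fy, fx = th / h, tw / w
    anns = [type(a)(bbox=a.bbox * np.array([fx, fy, fx, fy]), class_id=a.class_id)
            for a in sample.annotations]
    return ImageSample(image=img, annotations=anns, image_id=sample.image_id,
                       provenance=sample.provenance)


def make_mixed_batches(real: DetectionDataset, synthetic: DetectionDataset | None,
                       batch_size: int, rng: np.random.Generator,
                       multi_scale: tuple = ((128, 128),)):
    """Yield per-epoch batches mixing the two sources in proportion N_r:N_s.

    Each batch holds at least one sample from each nonempty source, samples
    tagged with provenance for loss routing; one multi-scale size is sampled
    per batch and applied to all its images. Each dataset is covered at most
    once per epoch (no oversampling).
    """
    n_r = len(real)
    n_s = len(synthetic) if synthetic is not None else 0
    r_idx = list(rng.permutation(n_r))
    s_idx = list(rng.permutation(n_s)) if n_s else []
    if n_s == 0:
        per_r, per_s = batch_size, 0
    else:
        per_r = max(1, round(batch_size * n_r / (n_r + n_s)))
        per_s = max(1, batch_size - per_r)
    while r_idx or s_idx:
        take_r = [r_idx.pop() for _ in range(min(per_r, len(r_idx)))]
        take_s = [s_idx.pop() for _ in range(min(per_s, len(s_idx)))]
        if not take_r and not take_s:
            break
        size = multi_scale[int(rng.integers(len(multi_scale)))]
        batch = ([_resize_sample(real.samples[i], size) for i in take_r]
                 + [_resize_sample(synthetic.samples[i], size) for i in take_s])
        yield batch, len(take_r)


def _batch_arrays(samples: list) -> np.ndarray:
    return np.stack([s.image for s in samples])


def _detection_loss(model: CTCDetectionModel, outputs: list, samples: list,
                    subset: np.ndarray, image_hw: tuple,
                    rng: np.random.Generator, config: TrainConfig):
    """Cross-entropy + smooth-L1 loss over a subset of the batch.

    Positive locations come from center-inside-box assignment on the
    closest-scale level; negatives are randomly subsampled at
    `neg_ratio` : 1 to positives so the background class does not swamp the
    mean cross-entropy.
    """
    k = model.config.n_classes
    h, w = image_hw
    shapes = model.level_shapes(h, w)
    strides = model.config.strides
    sel_img, sel_loc, sel_cls, lvl_of = [], [], [], []
    box_terms = []
    n_pos_total = 0
    per_level_targets = {
        i: L.assign_targets(samples[i].annotations, shapes, strides, k)
        for i in subset
    }
    for li, ((cls_logits, box_raw), (hl, wl)) in enumerate(zip(outputs, shapes)):
        n = cls_logits.shape[0]
        ll = hl * wl
        flat_logits = cls_logits.reshape(n, k + 1, ll).transpose(0, 2, 1)
        flat_box = box_raw.reshape(n, 4, ll).transpose(0, 2, 1)
        img_ids, loc_ids, cls_ids = [], [], []
        pos_img, pos_loc, pos_tgt = [], [], []
        for i in subset:
            tgt = per_level_targets[i][li]
            pos = tgt["pos"].ravel()
            pos_where = np.nonzero(pos)[0]
            n_pos = pos_where.size
            n_pos_total += n_pos
            neg_where = np.nonzero(~pos)[0]
            n_neg = min(neg_where.size,
                        max(config.neg_ratio * n_pos, config.min_negatives))
            neg_take = rng.choice(neg_where, size=n_neg, replace=False)
            locs = np.concatenate([pos_where, neg_take])
            img_ids.append(np.full(locs.size, i))
            loc_ids.append(locs)
            cls_ids.append(tgt["cls"].ravel()[locs])
            if n_pos:
                pos_img.append(np.full(n_pos, i))
                pos_loc.append(pos_where)
                pos_tgt.append(tgt["box"].reshape(4, ll).T[pos_where])
        if img_ids:
            ii = np.concatenate(img_ids)
            jj = np.concatenate(loc_ids)
            cc = np.concatenate(cls_ids)
            logits = flat_logits[(ii, jj)]          # (S, K+1)
            sel_img.append(logits)
            onehot = np.zeros((cc.size, k + 1))
            onehot[np.arange(cc.size), cc] = 1.0
            sel_cls.append(onehot)
        if pos_img:
            pi = np.concatenate(pos_img)
            pj = np.concatenate(pos_loc)
            pt = np.concatenate(pos_tgt)
            pred = flat_box[(pi, pj)]               # (P, 4)
            box_terms.append(L.box_loss(pred, Tensor(pt.astype(np.float32))))
    if not sel_img:
        raise ValueError("empty subset")
    from ._tensor import concat as t_concat
    logits_all = sel_img[0] if len(sel_img) == 1 else t_concat(sel_img, axis=0)
    onehot_all = np.concatenate(sel_cls)
    probs = logits_all.softmax(axis=-1)
    lc = L.classification_loss(Tensor(onehot_all.astype(np.float32)), probs)
    if box_terms:
        lb = box_terms[0]
        for t in box_terms[1:]:
            lb = lb + t
        lb = lb * (1.0 / max(1, n_pos_total))
    else:
        lb = Tensor(np.zeros(()))
    return lc, lb, n_pos_total


def _photometric_augment(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Noise + channel gain; spatially aligned with the input by construction."""
    gains = rng.uniform(0.9, 1.1, size=(images.shape[0], 1, 1, 3))
    noise = rng.normal(0, 4.0, size=images.shape)
    return np.clip(images.astype(np.float64) * gains + noise, 0, 255).astype(np.uint8)


def train(model: CTCDetectionModel, real: DetectionDataset,
          synthetic: DetectionDataset | None, config: TrainConfig):
    """Train with mixed batches and the sample-size-weighted loss.

    Returns (model, history); `history` is a list of per-iteration records
    (iteration, epoch, lr, total loss and its components, mixture weights).
    The model ends at the weights with the best validation mAP@0.5.
    """
    rng = np.random.default_rng(config.seed)
    mixed = synthetic is not None and len(synthetic) > 0
    n_r = len(real)
    n_s = len(synthetic) if mixed else 0
    weights = L.mixture_weights(n_r, n_s) if mixed else None

    # seeded validation split from the real source
    n_val = max(1, int(round(config.val_fraction * n_r)))
    order = rng.permutation(n_r)
    val_ids = set(order[:n_val].tolist())
    train_real = DetectionDataset([s for i, s in enumerate(real.samples)
                                   if i not in val_ids], real.class_names)
    val_ds = DetectionDataset([s for i, s in enumerate(real.samples)
                               if i in val_ids], real.class_names)

    opt = AdamW(model.parameters(), lr=config.base_lr,
                weight_decay=config.weight_decay)
    history = []
    iteration = 0
    best = (-1.0, None)
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        opt.lr = lr
        for batch, n_real_in_batch in make_mixed_batches(
                train_real, synthetic if mixed else None, config.batch_size,
                rng, config.multi_scale):
            images = _batch_arrays(batch)
            hw = images.shape[1:3]
            x = model.normalize(images)
            outputs = model.forward(x)
            real_subset = np.arange(n_real_in_batch)
            synth_subset = np.arange(n_real_in_batch, len(batch))
            if mixed and synth_subset.size and real_subset.size:
                lc_r, lb_r, _ = _detection_loss(model, outputs, batch,
                                                real_subset, hw, rng, config)
                lc_s, lb_s, _ = _detection_loss(model, outputs, batch,
                                                synth_subset, hw, rng, config)
                l_real = lc_r + lb_r
                l_syn = lc_s + lb_s
                if config.lambda_consistency > 0:
                    aug = _photometric_augment(images[synth_subset], rng)
                    out_aug = model.forward(model.normalize(aug))
                    reg = _consistency_term(model, outputs, out_aug, synth_subset)
                else:
                    reg = Tensor(np.zeros(()))
                total = (weights.w_real * l_real + weights.w_synthetic * l_syn
                         + config.lambda_consistency * reg)
                record = L.LossBreakdown(
                    total=float(total.data), class_term=float((lc_r + lc_s).data),
                    box_term=float((lb_r + lb_s).data),
                    real_term=float(l_real.data), synthetic_term=float(l_syn.data),
                    regularizer=float(reg.data), w_real=weights.w_real,
                    w_synthetic=weights.w_synthetic)
            else:
                lc, lb, _ = _detection_loss(model, outputs, batch,
                                            np.arange(len(batch)), hw, rng, config)
                raw = lc + lb
                if mixed:
                    # tail batch holding a single source: weight it as usual
                    only_synth = synth_subset.size > 0
                    w = weights.w_synthetic if only_synth else weights.w_real
                    total = raw * w
                    record = L.LossBreakdown(
                        total=float(total.data), class_term=float(lc.data),
                        box_term=float(lb.data),
                        real_term=0.0 if only_synth else float(raw.data),
                        synthetic_term=float(raw.data) if only_synth else 0.0,
                        w_real=weights.w_real, w_synthetic=weights.w_synthetic)
                else:
                    total = raw
                    record = L.LossBreakdown(total=float(total.data),
                                             class_term=float(lc.data),
                                             box_term=float(lb.data),
                                             real_term=float(total.data))
            if not np.isfinite(record.total):
                raise RuntimeError(
                    f"training diverged at iteration {iteration}: loss={record.total}"
                    f" (lr={lr}, epoch={epoch})")
            model.zero_grad()
            total.backward()
            opt.step()
            history.append({"iteration": iteration, "epoch": epoch, "lr": lr,
                            **record.__dict__})
            iteration += 1
        # validation checkpointing
        preds = predict_dataset(model, val_ds,
                                score_threshold=config.score_threshold)
        records = evaluate_images(preds, val_ds, seed=config.seed)
        val_map, _ = map_at_50(records)
        if not np.isnan(val_map) and val_map > best[0]:
            best = (val_map, copy.deepcopy(model.state_dict()))
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def _consistency_term(model, outputs, outputs_aug, synth_subset):
    """Mean squared difference of per-location class probabilities."""
    from ._tensor import concat as t_concat

    terms_a, terms_b = [], []
    k = model.config.n_classes
    for (cls_a, _), (cls_b, _) in zip(outputs, outputs_aug):
        pa = cls_a.softmax(axis=1).transpose(0, 2, 3, 1)  # (N, H, W, K+1)
        pb = cls_b.softmax(axis=1).transpose(0, 2, 3, 1)  # (M, H, W, K+1)
        pa = pa.reshape(pa.shape[0], -1, k + 1)[(synth_subset,)].reshape(-1, k + 1)
        pb = pb.reshape(-1, k + 1)
        terms_a.append(pa)
        terms_b.append(pb)
    a = t_concat(terms_a, axis=0)
    b = t_concat(terms_b, axis=0)
    return L.consistency_regularizer(a, b)


def predict_dataset(model: CTCDetectionModel, dataset: DetectionDataset,
                    score_threshold: float = 0.3, nms_iou: float = 0.5,
                    batch_size: int = 8) -> list:
    """Run inference over a dataset; returns one Prediction per image."""
    preds = []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset.samples[start:start + batch_size]
        images = np.stack([s.image for s in chunk])
        preds.extend(model.predict(images, score_threshold=score_threshold,
                                   nms_iou=nms_iou,
                                   image_ids=[s.image_id for s in chunk]))
    return preds
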