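"""The detection framework: hierarchical windowed-attention backbone, pyramid
scale adapter, deformable-convolution shape adapter, and a dense task head.

The backbone follows the Swin design: non-overlapping patch embedding with a
learned absolute positional embedding, four stages of windowed multi-head
self-attention blocks (alternating regular and shifted windows) with patch
merging between stages, producing features at strides 4/8/16/32 and widths
D, 2D, 4D, 8D. The scale adapter is a feature pyramid (1x1 laterals,
top-down nearest-neighbor upsample-and-add, 3x3 smoothing). The shape
adapter applies, per pyramid level, a 3x3 deformable convolution whose
per-location sampling offsets are predicted by a parallel convolution. The
head is a shared trunk of 3x3 convolutions followed by two per-location
projections: a (K+1)-way softmax classifier (background included) and an
anchor-free box regressor decoding distances to the four box sides against
the location's stride.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._tensor import Tensor, concat, conv2d, deform_sample
from .data import Prediction
from .errors import ShapeError

__all__ = ["ModelConfig", "CTCDetectionModel", "count_parameters",
           "count_flops", "nms", "TINY_TEST", "PAPER_BASE"]


@dataclass(frozen=True)
class ModelConfig:
    patch_size: int = 4
    embed_dim: int = 32
    stage_depths: tuple = (1, 1, 1, 1)
    stage_heads: tuple = (1, 2, 4, 8)
    window_size: int = 4
    pyramid_channels: int = 32
    n_classes: int = 2
    head_convs: int = 2
    head_width: int = 32
    pos_grid: int = 32          # side of the learned positional-embedding grid
    mlp_ratio: float = 4.0
    variant: str = "tiny-test"

    @property
    def stage_dims(self) -> tuple:
        return tuple(self.embed_dim * 2**i for i in range(4))

    @property
    def strides(self) -> tuple:
        p = self.patch_size
        return (p, 2 * p, 4 * p, 8 * p)


# CPU-friendly default for tests and examples.
TINY_TEST = ModelConfig()

# The published "base" configuration of the backbone, with a 256-channel
# pyramid, per-level deformable adapters, and a 4-conv head whose width is
# chosen so the trainable-parameter total lands on the printed 92.97 M.
PAPER_BASE = ModelConfig(
    patch_size=4, embed_dim=128, stage_depths=(2, 2, 18, 2),
    stage_heads=(4, 8, 16, 32), window_size=7, pyramid_channels=256,
    n_classes=1, head_convs=4, head_width=92, pos_grid=56,
    variant="paper-base",
)


def get_config(variant: str) -> ModelConfig:
    if variant in ("tiny-test", "tiny_test"):
        return TINY_TEST
    if variant in ("paper-base", "paper_base"):
        return PAPER_BASE
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------
class PatchEmbed(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        from ._tensor import Parameter
        p, d = cfg.patch_size, cfg.embed_dim
        self.proj = nn.Conv2d(3, d, p, rng, stride=p)
        self.pos = Parameter(nn.trunc_normal(rng, (cfg.pos_grid, cfg.pos_grid, d)))
        self.patch_size = p

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 3, H, W) -> (N, H/P, W/P, D) tokens with positional embedding."""
        n, _, h, w = x.shape
        p = self.patch_size
        if h % p or w % p:
            raise ShapeError(f"input sides must be divisible by {p}; "
                             f"pad to ({-(-h // p) * p}, {-(-w // p) * p})")
        tok = self.proj(x).transpose(0, 2, 3, 1)  # (N, Hp, Wp, D)
        hp, wp = tok.shape[1], tok.shape[2]
        g = self.pos.shape[0]
        if (hp, wp) == (g, g):
            pos = self.pos
        else:  # nearest-neighbor resampling of the learned grid
            iy = np.clip((np.arange(hp) * g / hp).astype(int), 0, g - 1)
            ix = np.clip((np.arange(wp) * g / wp).astype(int), 0, g - 1)
            pos = self.pos[np.ix_(iy, ix)]
        return tok + pos


class WindowAttention(nn.Module):
    def __init__(self, dim: int, heads: int, window: int, rng):
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        from ._tensor import Parameter
        self.rel_bias = Parameter(nn.trunc_normal(rng, ((2 * window - 1) ** 2, heads)))
        self.heads = heads
        self.window = window
        self.dim = dim
        coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :] + window - 1
        self._bias_index = (rel[0] * (2 * window - 1) + rel[1]).astype(np.int64)

    def __call__(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """xw: (B, M, C) windowed tokens; mask: (nW, M, M) additive or None."""
        b, m, c = xw.shape
        h = self.heads
        dh = c // h
        qkv = self.qkv(xw).reshape(b, m, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, M, dh)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        bias = self.rel_bias[self._bias_index.ravel()].reshape(m, m, h).transpose(2, 0, 1)
        attn = attn + bias
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(b // nw, nw, h, m, m) + Tensor(
                mask[:, None].astype(np.float32))
            attn = attn.reshape(b, h, m, m)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, m, c)
        return self.proj(out)


def _shift_mask(hp: int, wp: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask for shifted-window partitions."""
    img = np.zeros((hp, wp))
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    win = img.reshape(hp // window, window, wp // window, window)
    win = win.transpose(0, 2, 1, 3).reshape(-1, window * window)
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff != 0, -100.0, 0.0)


class SwinBlock(nn.Module):
    def __init__(self, dim: int, heads: int, window: int, shift: int, rng,
                 mlp_ratio: float = 4.0):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)
        self.window = window
        self.shift = shift

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, H, W, C)."""
        n, h, w, c = x.shape
        ws = self.window
        y = self.norm1(x)
        # pad bottom/right to window multiples; cropped again after attention
        ph, pw = (-h) % ws, (-w) % ws
        if ph or pw:
            y = y.pad_end({1: ph, 2: pw})
        hp, wp = h + ph, w + pw
        shift = self.shift if (hp > ws and wp > ws) else 0
        if shift:
            y = y.roll((-shift, -shift), axis=(1, 2))
            mask = _shift_mask(hp, wp, ws, shift)
        else:
            mask = None
        nh, nw_ = hp // ws, wp // ws
        yw = (y.reshape(n, nh, ws, nw_, ws, c).transpose(0, 1, 3, 2, 4, 5)
               .reshape(n * nh * nw_, ws * ws, c))
        yw = self.attn(yw, mask)
        y = (yw.reshape(n, nh, nw_, ws, ws, c).transpose(0, 1, 3, 2, 4, 5)
               .reshape(n, hp, wp, c))
        if shift:
            y = y.roll((shift, shift), axis=(1, 2))
        if ph or pw:
            y = y[:, :h, :w, :]
        x = x + y
        z = self.norm2(x)
        z = self.fc2(self.fc1(z).gelu())
        return x + z


class PatchMerging(nn.Module):
    def __init__(self, dim: int, rng):
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        x = (x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
              .reshape(n, h // 2, w // 2, 4 * c))
        return self.reduce(self.norm(x))


class Backbone(nn.Module):
    """Four hierarchical stages of windowed attention blocks."""

    def __init__(self, cfg: ModelConfig, rng):
        self.stages = []
        self.merges = []
        self.out_norms = []
        for i, (depth, heads) in enumerate(zip(cfg.stage_depths, cfg.stage_heads)):
            dim = cfg.stage_dims[i]
            blocks = [SwinBlock(dim, heads, cfg.window_size,
                                0 if d % 2 == 0 else cfg.window_size // 2,
                                rng, cfg.mlp_ratio)
                      for d in range(depth)]
            self.stages.append(blocks)
            self.out_norms.append(nn.LayerNorm(dim))
            if i < 3:
                self.merges.append(PatchMerging(dim, rng))

    def named_parameters(self, prefix: str = ""):
        for i, blocks in enumerate(self.stages):
            for j, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}.stage{i}.block{j}"
                                                if prefix else f"stage{i}.block{j}")
        for i, mg in enumerate(self.merges):
            yield from mg.named_parameters(f"{prefix}.merge{i}" if prefix else f"merge{i}")
        for i, nrm in enumerate(self.out_norms):
            yield from nrm.named_parameters(f"{prefix}.norm{i}" if prefix else f"norm{i}")

    def __call__(self, tok: Tensor) -> list:
        """tokens (N, Hp, Wp, D) -> list of 4 maps (N, C_i, H_i, W_i)."""
        outs = []
        x = tok
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            outs.append(self.out_norms[i](x).transpose(0, 3, 1, 2))
            if i < 3:
                x = self.merges[i](x)
        return outs


class ScaleAdapter(nn.Module):
    """Feature pyramid: 1x1 laterals, top-down upsample-and-add, 3x3 smoothing."""

    def __init__(self, in_dims, channels: int, rng):
        self.laterals = [nn.Conv2d(d, channels, 1, rng) for d in in_dims]
        self.outputs = [nn.Conv2d(channels, channels, 3, rng, padding=1)
                        for _ in in_dims]

    def __call__(self, feats: list) -> list:
        lat = [l(f) for l, f in zip(self.laterals, feats)]
        merged = [lat[-1]]
        for i in range(len(lat) - 2, -1, -1):
            merged.insert(0, lat[i] + merged[0].upsample2x_nearest())
        return [o(m) for o, m in zip(self.outputs, merged)]


class DeformConv2d(nn.Module):
    """3x3 deformable convolution with offsets from a parallel conv branch.

    With the offset branch forced to zero this is exactly a standard 3x3
    convolution (the zero-initialization used at training start).
    """

    def __init__(self, channels: int, rng):
        self.offset_conv = nn.Conv2d(channels, 18, 3, rng, padding=1)
        self.weight_conv = nn.Conv2d(9 * channels, channels, 1, rng)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        off = self.offset_conv(x)  # (N, 18, H, W): (dy, dx) per tap
        return self.weight_conv(deform_sample(x, off))

    def equivalent_standard_kernel(self) -> np.ndarray:
        """The (Co, C, 3, 3) kernel this layer equals when offsets are zero."""
        co = self.weight_conv.weight.data.shape[0]
        c = self.channels
        return (self.weight_conv.weight.data.reshape(co, 9, c)
                .transpose(0, 2, 1).reshape(co, c, 3, 3))


class ShapeAdapter(nn.Module):
    def __init__(self, channels: int, n_levels: int, rng):
        self.convs = [DeformConv2d(channels, rng) for _ in range(n_levels)]

    def __call__(self, pyramid: list) -> list:
        return [conv(p) for conv, p in zip(self.convs, pyramid)]


class DetectionHead(nn.Module):
    """Shared conv trunk + per-location class and box projections."""

    def __init__(self, cfg: ModelConfig, rng):
        chans = [cfg.pyramid_channels] + [cfg.head_width] * cfg.head_convs
        self.trunk = [nn.Conv2d(ci, co, 3, rng, padding=1)
                      for ci, co in zip(chans[:-1], chans[1:])]
        self.cls_proj = nn.Conv2d(cfg.head_width, cfg.n_classes + 1, 1, rng)
        self.box_proj = nn.Conv2d(cfg.head_width, 4, 1, rng)

    def __call__(self, pyramid: list) -> list:
        out = []
        for p in pyramid:
            f = p
            for conv in self.trunk:
                f = conv(f).relu()
            out.append((self.cls_proj(f), self.box_proj(f)))
        return out


class CTCDetectionModel(nn.Module):
    """End-to-end detector; see the module docstring for the architecture."""

    def __init__(self, config: ModelConfig = TINY_TEST, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.patch_embed = PatchEmbed(config, rng)
        self.backbone = Backbone(config, rng)
        self.scale_adapter = ScaleAdapter(config.stage_dims,
                                          config.pyramid_channels, rng)
        self.shape_adapter = ShapeAdapter(config.pyramid_channels, 4, rng)
        self.head = DetectionHead(config, rng)

    # exclude non-module attrs from parameter discovery
    def named_parameters(self, prefix: str = ""):
        for name in ("patch_embed", "backbone", "scale_adapter",
                     "shape_adapter", "head"):
            mod = getattr(self, name)
            yield from mod.named_parameters(f"{prefix}.{name}" if prefix else name)

    @staticmethod
    def normalize(images: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> float32 (N, 3, H, W), zero-centered."""
        x = np.asarray(images, dtype=np.float32) / 255.0
        x = (x - 0.5) / 0.25
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, x) -> list:
        """Normalized input (N, 3, H, W) -> per-level (class_logits, box_raw)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        n, _, h, w = x.shape
        div = self.config.patch_size * 8
        if h % div or w % div:
            raise ShapeError(f"input sides must be divisible by {div}; "
                             f"pad to ({-(-h // div) * div}, {-(-w // div) * div})")
        tok = self.patch_embed(x)
        feats = self.backbone(tok)
        pyramid = self.scale_adapter(feats)
        pyramid = self.shape_adapter(pyramid)
        return self.head(pyramid)

    def level_shapes(self, h: int, w: int) -> list:
        return [(h // s, w // s) for s in self.config.strides]

    def decode(self, outputs: list, image_hw: tuple) -> list:
        """Per-level raw outputs -> (class_probs, boxes) numpy arrays.

        Box decoding is anchor-free: at each location the four regressed
        values are log-distances to the box sides in stride units, so zero
        output decodes to the location's prior box (side 2 x stride).
        """
        h, w = image_hw
        results = []
        for (cls_logits, box_raw), s in zip(outputs, self.config.strides):
            probs = cls_logits.softmax(axis=1).data  # (N, K+1, Hl, Wl)
            n, _, hl, wl = probs.shape
            cy = (np.arange(hl) + 0.5) * s
            cx = (np.arange(wl) + 0.5) * s
            d = np.exp(np.clip(box_raw.data, -8, 8)) * s  # (N, 4, Hl, Wl)
            x0 = np.clip(cx[None, None, :] - d[:, 0], 0, w)
            y0 = np.clip(cy[None, :, None] - d[:, 1], 0, h)
            x1 = np.clip(cx[None, None, :] + d[:, 2], 0, w)
            y1 = np.clip(cy[None, :, None] + d[:, 3], 0, h)
            boxes = np.stack([x0, y0, x1, y1], axis=1)
            results.append((probs, boxes))
        return results

    def predict(self, images, score_threshold: float = 0.3,
                nms_iou: float = 0.5, image_ids=None) -> list:
        """uint8 images (N, H, W, 3) -> list of Prediction with NMS applied."""
        images = np.asarray(images)
        outputs = self.forward(self.normalize(images))
        decoded = self.decode(outputs, images.shape[1:3])
        n = images.shape[0]
        k = self.config.n_classes
        preds = []
        for i in range(n):
            boxes, scores, classes, probs = [], [], [], []
            for lvl_probs, lvl_boxes in decoded:
                p = lvl_probs[i].reshape(k + 1, -1).T       # (L, K+1)
                bx = lvl_boxes[i].reshape(4, -1).T          # (L, 4)
                fg = p[:, :k]
                best = fg.argmax(axis=1)
                score = fg[np.arange(len(best)), best]
                keep = ((score >= score_threshold)
                        & (bx[:, 2] > bx[:, 0]) & (bx[:, 3] > bx[:, 1]))
                boxes.append(bx[keep])
                scores.append(score[keep])
                classes.append(best[keep])
                probs.append(p[keep])
            boxes = np.concatenate(boxes) if boxes else np.zeros((0, 4))
            scores = np.concatenate(scores) if scores else np.zeros(0)
            classes = np.concatenate(classes) if classes else np.zeros(0, dtype=int)
            probs = np.concatenate(probs) if probs else np.zeros((0, k + 1))
            keep = nms(boxes, scores, classes, nms_iou)
            preds.append(Prediction(
                boxes=boxes[keep], scores=scores[keep], class_ids=classes[keep],
                class_probs=probs[keep],
                image_id=(image_ids[i] if image_ids is not None else i)))
        return preds

    # -- checkpointing -------------------------------------------------
    def save(self, path):
        import json
        from dataclasses import asdict
        state = self.state_dict()
        np.savez(path, __config__=json.dumps(asdict(self.config)),
                 **{k: v for k, v in state.items()})

    @classmethod
    def load(cls, path) -> "CTCDetectionModel":
        import json
        with np.load(path, allow_pickle=False) as z:
            cfg_dict = json.loads(str(z["__config__"]))
            for key in ("stage_depths", "stage_heads"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


def nms(boxes: np.ndarray, scores: np.ndarray, classes: np.ndarray,
        iou_threshold: float = 0.5) -> np.ndarray:
    """Greedy per-class non-maximum suppression; returns kept indices."""
    keep = []
    for c in np.unique(classes):
        idx = np.where(classes == c)[0]
        order = idx[np.argsort(-scores[idx], kind="stable")]
        taken = []
        for i in order:
            ok = True
            for j in taken:
                if _iou_xyxy(boxes[i], boxes[j]) > iou_threshold:
                    ok = False
                    break
            if ok:
                taken.append(i)
        keep.extend(taken)
    return np.array(sorted(keep), dtype=int)


def _iou_xyxy(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / ((a[2] - a[0]) * (a[3] - a[1])
                    + (b[2] - b[0]) * (b[3] - b[1]) - inter)


def count_parameters(model) -> int:
    """Total trainable parameter count."""
    return model.n_parameters()


def count_flops(config: ModelConfig, input_side: int) -> int:
    """Analytic multiply-accumulate count at a square input side.

    Covers the patch-embedding projection, attention qkv/proj and the two
    attention matmuls, MLPs, patch merging, pyramid and deformable convs,
    and the head convolutions and projections.
    """
    p = config.patch_size
    side = input_side // p
    total = (p * p * 3) * config.embed_dim * side * side  # patch embed
    dims = config.stage_dims
    ws2 = config.window_size**2
    s = side
    for i, (depth, _h) in enumerate(zip(config.stage_depths, config.stage_heads)):
        c = dims[i]
        t = s * s
        per_block = (3 * t * c * c          # qkv
                     + 2 * t * ws2 * c      # q@k^T and attn@v
                     + t * c * c            # proj
                     + 2 * t * c * int(config.mlp_ratio * c))  # mlp
        total += depth * per_block
        if i < 3:
            total += (t // 4) * (4 * c) * (2 * c)  # patch merging
            s //= 2
    # pyramid
    pc = config.pyramid_channels
    sides = [side // 2**i for i in range(4)]
    for c, sd in zip(dims, sides):
        total += sd * sd * c * pc               # lateral 1x1
        total += sd * sd * 9 * pc * pc          # output 3x3
        total += sd * sd * 9 * pc * 18          # offset branch
        total += sd * sd * 9 * pc * pc          # deformable conv
    # head (applied at every level)
    hw = config.head_width
    chans = [pc] + [hw] * config.head_convs
    for sd in sides:
        for ci, co in zip(chans[:-1], chans[1:]):
            total += sd * sd * 9 * ci * co
        total += sd * sd * hw * (config.n_classes + 1)
        total += sd * sd * hw * 4
    return int(total)
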