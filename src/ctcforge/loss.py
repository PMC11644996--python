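"""Detection losses, real/synthetic mixture weighting, consistency regularizer.

Single-source training minimizes L = L_c + L_b (cross-entropy classification
plus smooth-L1 box regression). When real and synthetic data are mixed, the
per-source losses are combined as L = w_r*L_r + w_s*L_s with weights
proportional to the source sample sizes, optionally plus a consistency
regularizer that penalizes squared output differences between an input and
its photometrically augmented copy.

All loss operations accept either numpy arrays (returning a float) or
autodiff tensors (returning a differentiable Tensor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .errors import ShapeError

__all__ = ["LossBreakdown", "MixtureWeights", "classification_loss", "box_loss",
           "mixture_weights", "consistency_regularizer", "mixed_loss",
           "single_source_loss", "assign_targets"]

_EPS = 1e-7


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


@dataclass(frozen=True)
class MixtureWeights:
    n_real: int
    n_synthetic: int
    w_real: float
    w_synthetic: float


@dataclass
class LossBreakdown:
    total: float
    class_term: float = 0.0
    box_term: float = 0.0
    real_term: float = 0.0
    synthetic_term: float = 0.0
    regularizer: float = 0.0
    w_real: float = 1.0
    w_synthetic: float = 0.0


def classification_loss(y, y_hat, eps: float = _EPS):
    """Mean cross-entropy.

    1-D inputs: binary labels y in {0,1} against probabilities y_hat,
    -(1/N) sum[y log yh + (1-y) log(1-yh)] with yh clamped to [eps, 1-eps].
    2-D inputs: one-hot (or soft) rows against probability rows,
    -(1/N) sum_i sum_k y_ik log yh_ik.
    """
    tensor_mode = _is_tensor(y, y_hat)
    yt, yh = _wrap(y), _wrap(y_hat)
    if yt.shape != yh.shape:
        raise ShapeError(f"label shape {yt.shape} != prediction shape {yh.shape}")
    yh = yh.clip(eps, 1.0 - eps)
    if yt.ndim == 1:
        ll = yt * yh.log() + (1.0 - yt) * (1.0 - yh).log()
        out = -ll.mean()
    else:
        n = yt.shape[0]
        out = -(yt * yh.log()).sum() * (1.0 / n)
    return out if tensor_mode else float(out.data)


def smooth_l1(x, beta: float = 1.0):
    """Huber-style penalty: 0.5 x^2 / beta for |x| < beta, else |x| - 0.5 beta."""
    xt = _wrap(x)
    d = xt.data
    quad = np.abs(d) < beta
    # piecewise assembled with constant masks so gradients stay exact
    sq = xt * xt * (0.5 / beta)
    mask = Tensor(quad.astype(d.dtype))
    sign = Tensor(np.sign(d))
    lin = xt * sign - 0.5 * beta
    return sq * mask + lin * (1.0 - mask)


def box_loss(pred_boxes, target_boxes, beta: float = 1.0):
    """Sum of smooth-L1 penalties over all matched box coordinates."""
    tensor_mode = _is_tensor(pred_boxes, target_boxes)
    p, t = _wrap(pred_boxes), _wrap(target_boxes)
    if p.shape != t.shape:
        raise ShapeError(f"predicted shape {p.shape} != target shape {t.shape}")
    out = smooth_l1(p - t, beta=beta).sum()
    return out if tensor_mode else float(out.data)


def mixture_weights(n_real: int, n_synthetic: int) -> MixtureWeights:
    """Sample-size-proportional weights w_r = N_r/(N_r+N_s), w_s = N_s/(N_r+N_s)."""
    if n_real < 0 or n_synthetic < 0:
        raise ValueError("sample counts must be nonnegative")
    total = n_real + n_synthetic
    if total == 0:
        raise ValueError("degenerate mixture: N_r + N_s must be positive")
    return MixtureWeights(n_real, n_synthetic, n_real / total, n_synthetic / total)


def consistency_regularizer(y_hat, y_hat_aug):
    """(1/N) sum_j ||y_aug_j - y_j||^2 over aligned probability vectors."""
    tensor_mode = _is_tensor(y_hat, y_hat_aug)
    a, b = _wrap(y_hat), _wrap(y_hat_aug)
    if a.shape != b.shape:
        raise ShapeError(f"misaligned outputs: {a.shape} vs {b.shape}")
    n = a.shape[0] if a.ndim > 0 else 1
    diff = b - a
    out = (diff * diff).sum() * (1.0 / n)
    return out if tensor_mode else float(out.data)


def single_source_loss(class_term, box_term) -> LossBreakdown:
    """L = L_c + L_b."""
    lc = class_term if isinstance(class_term, float) else float(class_term.data)
    lb = box_term if isinstance(box_term, float) else float(box_term.data)
    return LossBreakdown(total=lc + lb, class_term=lc, box_term=lb)


def mixed_loss(real_loss, synthetic_loss, weights: MixtureWeights,
               lam: float = 1.0, regularizer=0.0) -> LossBreakdown:
    """L = w_r * L_r + w_s * L_s + lam * R."""
    lr = float(real_loss.data) if isinstance(real_loss, Tensor) else float(real_loss)
    ls = float(synthetic_loss.data) if isinstance(synthetic_loss, Tensor) else float(synthetic_loss)
    r = float(regularizer.data) if isinstance(regularizer, Tensor) else float(regularizer)
    for name, v in (("real", lr), ("synthetic", ls), ("regularizer", r)):
        if v < -1e-9:
            raise ValueError(f"negative {name} loss component: {v}")
    total = weights.w_real * lr + weights.w_synthetic * ls + lam * r
    return LossBreakdown(total=total, real_term=lr, synthetic_term=ls,
                         regularizer=r, w_real=weights.w_real,
                         w_synthetic=weights.w_synthetic)


# -- dense-head target assignment -------------------------------------
def assign_targets(annotations, level_shapes, strides, n_classes: int,
                   center_radius: float = 1.5):
    """Assign ground-truth boxes to dense pyramid locations.

    Each box goes to the pyramid level whose canonical object size
    (4 x stride) is nearest to the box's longer side in log scale; within
    that level, a location is positive when its center falls inside the box
    and within `center_radius` strides of the box center (center sampling:
    edge locations make poor regression targets and become negatives). Positive box targets are log(d / stride) for the distances
    d = (left, top, right, bottom) from the location center to the box
    sides. Overlap conflicts resolve to the smaller box.

    Returns a list over levels of dicts with integer class targets
    (`n_classes` = background), float box targets (4, H, W) and a boolean
    positive mask.
    """
    out = []
    for (h, w), s in zip(level_shapes, strides):
        out.append({
            "cls": np.full((h, w), n_classes, dtype=np.int64),
            "box": np.zeros((4, h, w), dtype=np.float64),
            "pos": np.zeros((h, w), dtype=bool),
            "area": np.full((h, w), np.inf),
        })
    log_canon = np.log2(4.0 * np.asarray(strides, dtype=float))
    for ann in annotations:
        x0, y0, x1, y1 = ann.bbox
        side = max(x1 - x0, y1 - y0)
        if side <= 0:
            continue
        lvl = int(np.argmin(np.abs(np.log2(side) - log_canon)))
        s = strides[lvl]
        h, w = level_shapes[lvl]
        tgt = out[lvl]
        ii = np.arange(h)
        jj = np.arange(w)
        cy = (ii + 0.5) * s
        cx = (jj + 0.5) * s
        bcx, bcy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        r = center_radius * s
        inside = ((cy[:, None] > max(y0, bcy - r)) & (cy[:, None] < min(y1, bcy + r))
                  & (cx[None, :] > max(x0, bcx - r)) & (cx[None, :] < min(x1, bcx + r)))
        area = (x1 - x0) * (y1 - y0)
        take = inside & (area < tgt["area"])
        if not take.any():
            continue
        ys, xs = np.nonzero(take)
        tgt["area"][ys, xs] = area
        tgt["cls"][ys, xs] = ann.class_id
        tgt["pos"][ys, xs] = True
        d = np.stack([cx[xs] - x0, cy[ys] - y0, x1 - cx[xs], y1 - cy[ys]])
        tgt["box"][:, ys, xs] = np.log(np.maximum(d, 1e-3) / s)
    for tgt in out:
        del tgt["area"]
    return out
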