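"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the detection network: a small tensor
type recording an operation graph, with backward rules for the handful of
primitives the model needs (broadcast arithmetic, matmul, reductions,
reshapes, gather/scatter, im2col convolution). Dtypes are preserved, so
gradient checks can run in float64 while training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "conv2d", "gather_nhw",
           "deform_sample"]


def _as_array(x, dtype=None):
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    elif a.dtype == np.float64 or np.issubdtype(a.dtype, np.integer):
        a = a.astype(np.float64, copy=False) if a.dtype == np.float64 else a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- helpers -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray, own: bool = False):
        """Accumulate a gradient; `own=True` promises `g` is a fresh array
        not aliased by any other node, so it can be adopted without a copy."""
        if self.grad is None:
            if g.dtype != self.data.dtype:
                g = g.astype(self.data.dtype)
                own = True
            self.grad = g if own else g.copy()
        else:
            self.grad += g

    # -- graph ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.dtype))
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g, own=True)
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(_as_array(other, self.dtype))))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.dtype))
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), own=g.shape == self.data.shape)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), own=g.shape == other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.dtype))
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape), own=g.shape == self.data.shape)
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape), own=g.shape == other.data.shape)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor(_as_array(other, self.dtype)) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1), own=True)
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.dtype))
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape), own=ga.shape == self.data.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape), own=gb.shape == other.data.shape)

        out._backward = bw
        return out

    # -- elementwise nonlinearities -----------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * y, own=True)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data, own=True)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / y, own=True)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y), own=True)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accum(g * mask, own=True)
        return out

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        x = self.data
        c = x.dtype.type(np.sqrt(2.0 / np.pi))
        x2 = x * x
        inner = x * (c + (c * x.dtype.type(0.044715)) * x2)
        t = np.tanh(inner, out=inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y.astype(x.dtype, copy=False), _parents=(self,))

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accum(g * dy, own=True)

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y.astype(self.data.dtype, copy=False), _parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y), own=True)
        return out

    def clip(self, lo, hi):
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        out._backward = lambda g: self._accum(g * mask, own=True)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y.astype(self.data.dtype, copy=False), _parents=(self,))

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot), own=True)

        out._backward = bw
        return out

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls.astype(self.data.dtype, copy=False), _parents=(self,))
        sm = np.exp(ls)
        out._backward = lambda g: self._accum(g - sm * g.sum(axis=axis, keepdims=True), own=True)
        return out

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        y = xhat * gamma.data + beta.data
        out = Tensor(y.astype(x.dtype, copy=False), _parents=(self, gamma, beta))
        n = x.shape[-1]

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).reshape(-1, n).sum(axis=0), own=True)
            if beta.requires_grad:
                beta._accum(g.reshape(-1, n).sum(axis=0), own=True)
            if self.requires_grad:
                gx = g * gamma.data
                t1 = gx.sum(axis=-1, keepdims=True)
                t2 = (gx * xhat).sum(axis=-1, keepdims=True)
                self._accum(inv * (gx - t1 / n - xhat * t2 / n), own=True)

        out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def roll(self, shift, axis):
        out = Tensor(np.roll(self.data, shift, axis=axis), _parents=(self,))
        neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
        out._backward = lambda g: self._accum(np.roll(g, neg, axis=axis))
        return out

    def pad2d(self, ph: int, pw: int):
        """Zero-pad the last two axes symmetrically."""
        widths = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]
        out = Tensor(np.pad(self.data, widths), _parents=(self,))

        def bw(g):
            sl = (Ellipsis, slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw))
            self._accum(g[sl])

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice, type(Ellipsis))) for i in idx))

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:  # basic indexing never repeats elements
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accum(full, own=True)

        out._backward = bw
        return out

    def pad_end(self, axis_pads):
        """Zero-pad at the end of selected axes; `axis_pads` maps axis -> pad."""
        widths = [(0, axis_pads.get(i, 0)) for i in range(self.data.ndim)]
        out = Tensor(np.pad(self.data, widths), _parents=(self,))

        def bw(g):
            sl = tuple(slice(0, self.data.shape[i]) for i in range(self.data.ndim))
            self._accum(g[sl])

        out._backward = bw
        return out

    def upsample2x_nearest(self):
        """Nearest-neighbor 2x upsampling of an (N, C, H, W) map."""
        out = Tensor(self.data.repeat(2, axis=-2).repeat(2, axis=-1), _parents=(self,))

        def bw(g):
            n, c, h2, w2 = g.shape
            self._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)), own=True)

        out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def concat(tensors, axis=0):
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0):
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of (N,C,H,W) input with (Co,C,kh,kw) kernel."""
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    co, ci, kh, kw = wd.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    s = stride
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    ho = (xp.shape[2] - kh) // s + 1
    wo = (xp.shape[3] - kw) // s + 1
    if kh == kw == 1 and s == 1:
        col2 = xp.reshape(n, c, ho * wo)
    else:
        cols = np.empty((n, c, kh, kw, ho, wo), dtype=xd.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
        col2 = cols.reshape(n, c * kh * kw, ho * wo)
    w2 = wd.reshape(co, c * kh * kw)
    out_d = np.matmul(w2[None], col2)  # (N, Co, L)
    if bias is not None:
        out_d += bias.data[:, None]
    out_d = out_d.reshape(n, co, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_d, _parents=parents)

    def bw(g):
        gm = np.ascontiguousarray(g.reshape(n, co, ho * wo))
        if bias is not None and bias.requires_grad:
            bias._accum(gm.sum(axis=(0, 2)), own=True)
        if weight.requires_grad:
            gw = np.matmul(gm, col2.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(wd.shape), own=True)
        if x.requires_grad:
            dcol = np.matmul(w2.T[None], gm)  # (N, C*kh*kw, L)
            if kh == kw == 1 and s == 1:
                dxp = dcol.reshape(xp.shape)
            else:
                dcol = dcol.reshape(n, c, kh, kw, ho, wo)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcol[:, :, i, j]
            if padding:
                dxp = np.ascontiguousarray(dxp[:, :, padding:padding + h,
                                               padding:padding + w])
            x._accum(dxp, own=True)

    out._backward = bw
    return out


def gather_nhw(x: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """out[n, :, p] = x[n, :, iy[n, p], ix[n, p]] for flat spatial index p.

    `iy`/`ix` are integer arrays of shape (N, L); the output is (N, C, L).
    Gradient scatters with accumulation (multiple gathers of one source
    pixel sum their gradients).
    """
    n, c, h, w = x.data.shape
    idx = (iy * w + ix).astype(np.int64)  # (N, L)
    flat = x.data.reshape(n, c, h * w)
    out_d = np.take_along_axis(flat, idx[:, None, :], axis=2)
    out = Tensor(out_d, _parents=(x,))

    # combined (sample, pixel, channel) flat index, built once per node
    _ch = np.arange(c, dtype=np.int64)
    _off = (np.arange(n, dtype=np.int64) * (h * w))[:, None]

    def bw(g):
        if not x.requires_grad:
            return
        comb = (((idx + _off) * c)[:, :, None] + _ch).ravel()
        gv = np.ascontiguousarray(g.transpose(0, 2, 1)).ravel()  # (N, L, C) order
        dflat = np.bincount(comb, weights=gv, minlength=n * h * w * c)
        x._accum(np.ascontiguousarray(dflat.reshape(n, h * w, c).transpose(0, 2, 1))
                 .reshape(x.data.shape).astype(x.data.dtype, copy=False), own=True)

    out._backward = bw
    return out


def deform_sample(x: Tensor, offsets: Tensor) -> Tensor:
    """Bilinear sampling for a 3x3 deformable convolution.

    `x` is (N, C, H, W); `offsets` is (N, 18, H, W) holding (dy, dx) per
    kernel tap in row-major tap order. Returns (N, 9C, H, W): for tap k at
    output location (i, j), the input sampled at
    (i + a_k + dy_k(i,j), j + b_k + dx_k(i,j)) with (a_k, b_k) the rigid
    3x3 grid displacement, bilinearly interpolated with zero padding
    outside the frame. A 1x1 convolution of the result with the reshaped
    3x3 kernel completes the deformable convolution; zero offsets make it
    exactly the standard convolution.
    """
    n, c, h, w = x.data.shape
    if offsets.data.shape != (n, 18, h, w):
        raise ValueError("offsets must be (N, 18, H, W)")
    hw = h * w
    off = offsets.data.reshape(n, 9, 2, h, w)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    tap_dy = np.repeat(np.arange(-1, 2), 3).astype(x.data.dtype)
    tap_dx = np.tile(np.arange(-1, 2), 3).astype(x.data.dtype)
    py = off[:, :, 0] + tap_dy[None, :, None, None] + ii
    px = off[:, :, 1] + tap_dx[None, :, None, None] + jj
    y0 = np.floor(py)
    x0 = np.floor(px)
    fy = (py - y0).astype(x.data.dtype)
    fx = (px - x0).astype(x.data.dtype)
    flat = x.data.reshape(n, c, hw)

    def corner(dy, dx):
        iy = y0 + dy
        ix = x0 + dx
        valid = ((iy >= 0) & (iy < h) & (ix >= 0) & (ix < w))
        idx = (np.clip(iy, 0, h - 1) * w + np.clip(ix, 0, w - 1)).astype(np.int64)
        v = np.take_along_axis(flat, idx.reshape(n, 1, 9 * hw), axis=2)
        v = v.reshape(n, c, 9, h, w)
        wgt = valid.astype(x.data.dtype)
        return v, wgt, idx

    v00, m00, i00 = corner(0, 0)
    v01, m01, i01 = corner(0, 1)
    v10, m10, i10 = corner(1, 0)
    v11, m11, i11 = corner(1, 1)
    w00 = (1 - fy) * (1 - fx) * m00
    w01 = (1 - fy) * fx * m01
    w10 = fy * (1 - fx) * m10
    w11 = fy * fx * m11
    out_d = (v00 * w00[:, None] + v01 * w01[:, None]
             + v10 * w10[:, None] + v11 * w11[:, None])
    out = Tensor(np.ascontiguousarray(out_d.transpose(0, 2, 1, 3, 4))
                 .reshape(n, 9 * c, h, w), _parents=(x, offsets))

    def bw(g):
        gd = g.reshape(n, 9, c, h, w)
        gdt = np.ascontiguousarray(gd.transpose(0, 1, 3, 4, 2))  # (N,9,H,W,C)
        if x.requires_grad:
            dflat = np.zeros(n * hw * c)
            ch = np.arange(c, dtype=np.int64)
            samp = (np.arange(n, dtype=np.int64) * hw).reshape(n, 1, 1, 1)
            for idx, wgt in ((i00, w00), (i01, w01), (i10, w10), (i11, w11)):
                comb = (((idx + samp) * c)[..., None] + ch).ravel()
                vals = (gdt * wgt[..., None]).ravel()
                dflat += np.bincount(comb, weights=vals, minlength=n * hw * c)
            dx_ = (dflat.reshape(n, hw, c).transpose(0, 2, 1)
                   .reshape(n, c, h, w).astype(x.data.dtype))
            x._accum(dx_, own=True)
        if offsets.requires_grad:
            # d(out)/d(fy) and d(out)/d(fx), contracted over channels
            gv = gd.transpose(0, 2, 1, 3, 4)  # (N, C, 9, H, W)
            dfy = ((gv * (v10 * m10[:, None] - v00 * m00[:, None])).sum(axis=1)
                   * (1 - fx)
                   + (gv * (v11 * m11[:, None] - v01 * m01[:, None])).sum(axis=1)
                   * fx)
            dfx = ((gv * (v01 * m01[:, None] - v00 * m00[:, None])).sum(axis=1)
                   * (1 - fy)
                   + (gv * (v11 * m11[:, None] - v10 * m10[:, None])).sum(axis=1)
                   * fy)
            doff = np.empty((n, 9, 2, h, w), dtype=offsets.data.dtype)
            doff[:, :, 0] = dfy
            doff[:, :, 1] = dfx
            offsets._accum(doff.reshape(n, 18, h, w), own=True)

    out._backward = bw
    return out
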