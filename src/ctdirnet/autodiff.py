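"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set needed by the registration network and its
losses: elementwise arithmetic, reductions, LeakyReLU, 3-D convolution (stride 1,
"same" padding), 2x max-pool / nearest-neighbour up-sampling, channel
concatenation, backward trilinear warping of a fixed volume by a displacement
field, and the squared forward-difference smoothness penalty.

Gradients propagate through a dynamically built tape; ``Tensor.backward`` runs a
topological sweep.  Arrays keep whatever float dtype they are given, so gradient
checks can run in float64 while training runs in float32.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a, b, value, da, db) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = value(a.data, b.data)
    req = a.requires_grad or b.requires_grad

    def backward(grad):
        if a.requires_grad:
            a._accumulate(_unbroadcast(da(grad, a.data, b.data), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(db(grad, a.data, b.data), b.data.shape))

    return Tensor(out_data, req, (a, b), backward if req else None)


def add(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def mul(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def div(a, b) -> Tensor:
    return _binary(
        a, b,
        lambda x, y: x / y,
        lambda g, x, y: g / y,
        lambda g, x, y: -g * x / (y * y),
    )


def absolute(a) -> Tensor:
    """|a| with the sign subgradient (0 at 0)."""
    a = as_tensor(a)
    out_data = np.abs(a.data)

    def backward(grad):
        a._accumulate(grad * np.sign(a.data))

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def total(a) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum()

    def backward(grad):
        a._accumulate(np.broadcast_to(grad, a.data.shape).astype(a.data.dtype))

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def mean(a) -> Tensor:
    a = as_tensor(a)
    n = a.data.size
    out_data = a.data.mean()

    def backward(grad):
        a._accumulate(np.broadcast_to(grad / n, a.data.shape).astype(a.data.dtype))

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out_data = np.where(pos, a.data, slope * a.data)

    def backward(grad):
        a._accumulate(np.where(pos, grad, slope * grad))

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


def concat(tensors) -> Tensor:
    """Concatenate along the channel (first) axis."""
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=0)
    req = any(t.requires_grad for t in tensors)

    def backward(grad):
        off = 0
        for t in tensors:
            c = t.data.shape[0]
            if t.requires_grad:
                t._accumulate(grad[off:off + c])
            off += c

    return Tensor(out_data, req, tuple(tensors), backward if req else None)


def narrow_channels(a, start: int, stop: int) -> Tensor:
    """Slice channels [start:stop] along the first axis."""
    a = as_tensor(a)
    out_data = a.data[start:stop]

    def backward(grad):
        full = np.zeros_like(a.data)
        full[start:stop] = grad
        a._accumulate(full)

    return Tensor(out_data, a.requires_grad, (a,), backward if a.requires_grad else None)


# -- convolution ------------------------------------------------------------


def conv3d(x, weight, bias) -> Tensor:
    """3-D convolution, stride 1, zero padding k//2 ("same" output size).

    ``x``: (Ci, D, H, W); ``weight``: (Co, Ci, k, k, k); ``bias``: (Co,).

    Computed as a sum of k^3 shifted (N, Ci) x (Ci, Co) matrix products rather
    than one huge im2col matrix: the column matrix for a full-resolution layer
    would dominate memory traffic, while the shifted products keep every
    temporary at the size of the input itself.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    ci, d, h, w = x.data.shape
    co, ci_w, k, _, _ = weight.data.shape
    if ci != ci_w:
        raise ValueError(f"conv3d channel mismatch: input {ci}, weight expects {ci_w}")
    pad = k // 2
    n = d * h * w
    kk = k * k * k
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))

    # stacked column matrix: one contiguous copy per kernel offset, one GEMM total
    cols = np.empty((kk, ci, n), dtype=x.data.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                cols[(a * k + b) * k + c] = xp[:, a:a + d, b:b + h, c:c + w].reshape(ci, n)
    cols = cols.reshape(kk * ci, n)
    # weight laid out to match: (Co, k, k, k, Ci) -> (Co, k^3 * Ci)
    wmat = np.ascontiguousarray(weight.data.transpose(0, 2, 3, 4, 1)).reshape(co, kk * ci)
    out_data = (wmat @ cols + bias.data[:, None]).reshape(co, d, h, w)
    req = x.requires_grad or weight.requires_grad or bias.requires_grad

    def backward(grad):
        gmat = grad.reshape(co, n)
        if bias.requires_grad:
            bias._accumulate(grad.sum(axis=(1, 2, 3)))
        if weight.requires_grad:
            gw = (gmat @ cols.T).reshape(co, k, k, k, ci).transpose(0, 4, 1, 2, 3)
            weight._accumulate(np.ascontiguousarray(gw))
        if x.requires_grad:
            gcols = (wmat.T @ gmat).reshape(kk, ci, d, h, w)
            gxp = np.zeros_like(xp)
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        gxp[:, a:a + d, b:b + h, c:c + w] += gcols[(a * k + b) * k + c]
            x._accumulate(gxp[:, pad:pad + d, pad:pad + h, pad:pad + w] if pad else gxp)

    return Tensor(out_data, req, (x, weight, bias), backward if req else None)


def maxpool2(x) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    x = as_tensor(x)
    c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(d, h, w)}")
    blocks = (
        x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, d // 2, h // 2, w // 2, 8)
    )
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        gblocks = np.zeros_like(blocks)
        np.put_along_axis(gblocks, idx[..., None], grad[..., None], axis=-1)
        gx = (
            gblocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        x._accumulate(gx)

    return Tensor(out_data, x.requires_grad, (x,), backward if x.requires_grad else None)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x up-sampling along all three spatial axes."""
    x = as_tensor(x)
    out_data = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(grad):
        c, d, h, w = x.data.shape
        x._accumulate(grad.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)))

    return Tensor(out_data, x.requires_grad, (x,), backward if x.requires_grad else None)


# -- warping ----------------------------------------------------------------


def warp_volume(volume: np.ndarray, dvf) -> Tensor:
    """Backward-warp a fixed 3-D volume by a displacement field (voxel units).

    ``output(p) = volume(p + g(p))`` by trilinear interpolation; sample
    coordinates are clamped to the grid border.  The gradient flows to the
    displacement field only (the volume is treated as constant data).
    """
    dvf = as_tensor(dvf)
    vol = np.asarray(volume)
    if dvf.data.shape != (3,) + vol.shape:
        raise ValueError(
            f"displacement field shape {dvf.data.shape} does not match volume {vol.shape}"
        )
    nz, ny, nx = vol.shape
    base = np.indices(vol.shape, dtype=dvf.data.dtype)
    raw = base + dvf.data
    inside = [
        (raw[c] >= 0) & (raw[c] <= (vol.shape[c] - 1)) for c in range(3)
    ]
    coords = [np.clip(raw[c], 0, vol.shape[c] - 1) for c in range(3)]
    lo = [np.minimum(np.floor(coords[c]).astype(np.intp), vol.shape[c] - 2)
          if vol.shape[c] > 1 else np.zeros(vol.shape, dtype=np.intp)
          for c in range(3)]
    fr = [coords[c] - lo[c] for c in range(3)]
    z0, y0, x0 = lo
    fz, fy, fx = fr
    c = {}
    for i in (0, 1):
        for j in (0, 1):
            for k in (0, 1):
                c[i, j, k] = vol[np.minimum(z0 + i, nz - 1),
                                 np.minimum(y0 + j, ny - 1),
                                 np.minimum(x0 + k, nx - 1)]
    wz = (1 - fz, fz)
    wy = (1 - fy, fy)
    wx = (1 - fx, fx)
    out_data = np.zeros_like(vol, dtype=dvf.data.dtype)
    for i in (0, 1):
        for j in (0, 1):
            for k in (0, 1):
                out_data = out_data + wz[i] * wy[j] * wx[k] * c[i, j, k]

    def backward(grad):
        dz = np.zeros_like(out_data)
        dy = np.zeros_like(out_data)
        dx = np.zeros_like(out_data)
        for j in (0, 1):
            for k in (0, 1):
                dz += wy[j] * wx[k] * (c[1, j, k] - c[0, j, k])
        for i in (0, 1):
            for k in (0, 1):
                dy += wz[i] * wx[k] * (c[i, 1, k] - c[i, 0, k])
        for i in (0, 1):
            for j in (0, 1):
                dx += wz[i] * wy[j] * (c[i, j, 1] - c[i, j, 0])
        g = np.stack([grad * dz * inside[0], grad * dy * inside[1], grad * dx * inside[2]])
        dvf._accumulate(g.astype(dvf.data.dtype))

    return Tensor(out_data, dvf.requires_grad, (dvf,),
                  backward if dvf.requires_grad else None)


def smoothness(dvf) -> Tensor:
    """Mean squared forward-difference gradient of a displacement field.

    ``L = (1 / 3N) * sum over components c, axes a, voxels p of
    (g_c(p + e_a) - g_c(p))^2`` with zero differences on each last-index face
    (no wraparound).  The 1/(3N) normalization makes the penalty independent of
    grid size, so its weight transfers across resolutions.
    """
    dvf = as_tensor(dvf)
    g = dvf.data
    if g.ndim != 4 or g.shape[0] != 3:
        raise ValueError(f"smoothness expects (3, nz, ny, nx), got {g.shape}")
    n = g[0].size
    diffs = [np.diff(g, axis=axis) for axis in (1, 2, 3)]
    out_data = np.asarray(sum(float((d * d).sum()) for d in diffs) / (3.0 * n),
                          dtype=g.dtype)

    def backward(grad):
        gg = np.zeros_like(g)
        scale = 2.0 * grad / (3.0 * n)
        for axis, d in zip((1, 2, 3), diffs):
            sl_lo = [slice(None)] * 4
            sl_hi = [slice(None)] * 4
            sl_lo[axis] = slice(0, g.shape[axis] - 1)
            sl_hi[axis] = slice(1, g.shape[axis])
            gg[tuple(sl_lo)] -= scale * d
            gg[tuple(sl_hi)] += scale * d
        dvf._accumulate(gg)

    return Tensor(out_data, dvf.requires_grad, (dvf,),
                  backward if dvf.requires_grad else None)
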