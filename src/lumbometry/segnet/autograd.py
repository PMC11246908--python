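"""A minimal reverse-mode autodiff engine on numpy arrays.

Implements exactly the operations the segmentation network needs: 2D
convolution (stride/padding/dilation, via im2col + BLAS), batch norm, SiLU /
sigmoid, elementwise arithmetic with broadcasting, channel concatenation,
average / global-average pooling, nearest-neighbour up-sampling, and the
reductions required to express Dice + cross-entropy losses.

Everything is float32 and fully deterministic: no threads, no hidden RNG.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "conv2d", "batch_norm2d", "silu", "sigmoid",
    "add", "mul", "concat", "avg_pool2d", "global_avg_pool", "upsample2x",
    "softmax", "tsum", "reshape",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this node (topological order)."""
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Small operator sugar used by the loss expressions.
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return Tensor(out_data, parents=(a,), backward=backward)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(a,), backward=backward)


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

    return Tensor(out_data, parents=(a,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# Convolution as tap-wise shift-and-matmul: one BLAS matmul per kernel tap
# on (almost) contiguous slices.  Far cheaper than materialising an im2col
# buffer at these feature-map sizes.
# ---------------------------------------------------------------------------

def _conv_geometry(h, w, kh, kw, stride, pad, dil):
    eff_kh, eff_kw = dil * (kh - 1) + 1, dil * (kw - 1) + 1
    oh = (h + 2 * pad - eff_kh) // stride + 1
    ow = (w + 2 * pad - eff_kw) // stride + 1
    return oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout."""
    n, _, h, w = x.shape
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, kernel wants {cin}")
    oh, ow = _conv_geometry(h, w, kh, kw, stride, padding, dilation)
    if padding:
        xp = np.zeros((n, cin, h + 2 * padding, w + 2 * padding), dtype=np.float32)
        xp[:, :, padding : padding + h, padding : padding + w] = x.data
    else:
        xp = x.data
    hp, wp = xp.shape[2], xp.shape[3]

    out_flat = np.zeros((n, cout, oh * ow), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            r0, c0 = i * dilation, j * dilation
            patch = np.ascontiguousarray(
                xp[:, :, r0 : r0 + oh * stride : stride,
                   c0 : c0 + ow * stride : stride]
            ).reshape(n, cin, oh * ow)
            out_flat += weight.data[:, :, i, j] @ patch
    out_data = out_flat.reshape(n, cout, oh, ow)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        need_gx, need_gw = x.requires_grad, weight.requires_grad
        if not (need_gx or need_gw):
            return
        gflat = np.ascontiguousarray(g.reshape(n, cout, oh * ow))
        gxp = np.zeros_like(xp) if need_gx else None
        gw = np.empty_like(weight.data) if need_gw else None
        for i in range(kh):
            for j in range(kw):
                r0, c0 = i * dilation, j * dilation
                patch = np.ascontiguousarray(
                    xp[:, :, r0 : r0 + oh * stride : stride,
                       c0 : c0 + ow * stride : stride]
                ).reshape(n, cin, oh * ow)
                if gw is not None:
                    gw[:, :, i, j] = np.einsum(
                        "nol,ncl->oc", gflat, patch, optimize=True
                    )
                if gxp is not None:
                    gpatch = (weight.data[:, :, i, j].T @ gflat).reshape(
                        n, cin, oh, ow
                    )
                    gxp[:, :, r0 : r0 + oh * stride : stride,
                        c0 : c0 + ow * stride : stride] += gpatch
        if gw is not None:
            weight._accumulate(gw)
        if gxp is not None:
            x._accumulate(
                gxp[:, :, padding : padding + h, padding : padding + w]
                if padding else gxp
            )

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, parents=parents, backward=backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays mutated in place when
    ``training`` is True.
    """
    c = x.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gs = gamma.data.reshape(1, c, 1, 1) * inv_std.reshape(1, c, 1, 1)
        if training:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            gxh = g * gamma.data.reshape(1, c, 1, 1)
            t1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
            t2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxh - t1 / m - xhat * t2 / m) * inv_std.reshape(1, c, 1, 1)
            x._accumulate(gx.astype(np.float32))
        else:
            x._accumulate(g * gs)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling (H, W divisible by k)."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial size {(h, w)} not divisible by {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accumulate(gx.astype(np.float32))

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / (h * w), x.shape).astype(np.float32))

    return Tensor(out_data, parents=(x,), backward=backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x up-sampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gx.astype(np.float32))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            x._accumulate((p * (g - dot)).astype(np.float32))

    return Tensor(p, parents=(x,), backward=backward)
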