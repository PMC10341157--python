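"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the segmentation network needs: elementwise
arithmetic, batched matmul, 2-D convolution (im2col), 2x2 max-pooling,
separable bilinear resizing, softmax, layer normalisation, and an Adam
optimiser.  Gradients are accumulated on a dynamically built tape and
released by :meth:`Tensor.backward`.

Arrays follow the (N, C, H, W) layout for image-like data and (..., features)
for token sequences.  float32 is the working precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Linear", "Conv2d", "LayerNorm",
    "InstanceNorm",
    "Adam", "astensor", "concat", "stack", "relu", "leaky_relu", "sigmoid",
    "softmax", "conv2d", "max_pool2", "bilinear_resize", "gather_hw",
    "layer_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(np.asarray(self.data).item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    def __mul__(self, other):
        other = astensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        return self * astensor(other) ** -1.0

    def __rtruediv__(self, other):
        return astensor(other) * self ** -1.0

    __radd__ = __add__
    __rmul__ = __mul__

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = _node(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    # -- reductions and elementwise --------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        out = _node(np.exp(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bw
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp with pass-through gradient strictly inside the bounds."""
        out = _node(np.clip(self.data, lo, hi), (self,))
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bw
        return out


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    t = Tensor(data)
    t.requires_grad = any(p.requires_grad for p in parents)
    if t.requires_grad:
        t._prev = tuple(p for p in parents if p.requires_grad or p._prev)
    return t


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


# -- functional ops -------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0), (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))
    out._backward = bw
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = _node(np.where(x.data > 0, x.data, slope * x.data), (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * np.where(x.data > 0, 1.0, slope).astype(x.data.dtype))
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    d = x.data
    s = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                 np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    out = _node(s, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1 - s))
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))
    out._backward = bw
    return out


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*k*k, oh*ow) by k*k strided slicing."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(cols: np.ndarray, xshape: tuple, k: int, s: int, p: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, h, w = xshape
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + s * oh:s, j:j + s * ow:s] += cols[:, :, i, j]
    return xp[:, :, p:p + h, p:p + w] if p else xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; x (N,C,H,W), w (O,C,k,k), b (O,)."""
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    oh = (h + 2 * padding - k) // stride + 1
    ow = (wd + 2 * padding - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2)) \
        if padding else x.data
    cols = _im2col(xp, k, stride, oh, ow)                    # (N, Ckk, L)
    wmat = w.data.reshape(o, -1)
    y = (wmat @ cols).reshape(n, o, oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents)

    def bw(g):
        gmat = g.reshape(n, o, oh * ow)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(gmat, cols, axes=([0, 2], [0, 2]))
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = wmat.T @ gmat                            # (N, Ckk, L)
            x._accum(_col2im(gcols, x.shape, k, stride, padding, oh, ow))
    out._backward = bw
    return out


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = _node(y, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(x.shape))
    out._backward = bw
    return out


def _resize_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (n_out, n_in)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    m[np.arange(n_out), lo] += 1 - t
    m[np.arange(n_out), hi] += t
    return m


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of (N, C, H, W) to (N, C, *size)."""
    n, c, h, w = x.shape
    oh, ow = size
    wr = _resize_matrix(h, oh, x.data.dtype)
    wc = _resize_matrix(w, ow, x.data.dtype)
    y = np.einsum("ph,nchw,qw->ncpq", wr, x.data, wc, optimize=True)
    out = _node(y, (x,))

    def bw(g):
        if x.requires_grad:
            x._accum(np.einsum("ph,ncpq,qw->nchw", wr, g, wc, optimize=True))
    out._backward = bw
    return out


def gather_hw(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Sample x (C, H, W) at integer sites -> (C, P); scatter-add backward."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    out = _node(x.data[:, rows, cols], (x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (slice(None), rows, cols), g)
            x._accum(full)
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor | None, beta: Tensor | None,
               eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis; affine optional."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc * (var + eps) ** -0.5
    if gamma is not None:
        xn = xn * gamma
    if beta is not None:
        xn = xn + beta
    return xn


# -- modules --------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            out.extend(_params_of(v))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        named = dict(self.named_parameters())
        for k, v in state.items():
            named[k].data = np.asarray(v, dtype=np.float32).reshape(named[k].shape)

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            yield from _named_params_of(v, prefix + name)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _params_of(v):
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_params_of(item))
        return out
    return []


def _named_params_of(v, name):
    if isinstance(v, Parameter):
        yield name, v
    elif isinstance(v, Module):
        for k, p in v.named_parameters(name + "."):
            yield k, p
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            yield from _named_params_of(item, f"{name}.{i}")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0, 1, (n_in, n_out)) * scale)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        fan_in = c_in * k * k
        self.w = Parameter(rng.normal(0, 1, (c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class InstanceNorm(Module):
    """Per-channel spatial normalisation with affine; the batch-size-1 norm."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.g = Parameter(np.ones((1, c, 1, 1)))
        self.b = Parameter(np.zeros((1, c, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.g + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, affine: bool = True):
        self.g = Parameter(np.ones(dim)) if affine else None
        self.b = Parameter(np.zeros(dim)) if affine else None

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.b)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
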