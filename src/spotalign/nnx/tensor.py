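"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small (tiny CNN / tiny transformer backbones,
self-normalizing MLPs), so a compact tape-based autograd over float64/float32
numpy arrays is sufficient and keeps the package fully deterministic on CPU.

Conventions
-----------
* A :class:`Tensor` wraps an ``np.ndarray`` and remembers the operations that
  produced it.  Calling :meth:`Tensor.backward` on a scalar accumulates
  gradients into every upstream tensor with ``requires_grad=True``.
* Broadcasting follows numpy; gradients are un-broadcast (summed) back to the
  operand shape.
* All primitives here are validated against central finite differences in the
  test suite.
"""

from __future__ import annotations

import numpy as np

# SELU fixed-point constants (drive activations toward zero mean, unit
# variance under lecun-normal initialization).
SELU_ALPHA = 1.6732632423543772
SELU_SCALE = 1.0507009873554805


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over broadcast (size-1) axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data)
        _attach(out, (self, other))

        def bwd(g):
            _accum(self, _unbroadcast(g, self.shape))
            _accum(other, _unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data)
        _attach(out, (self, other))

        def bwd(g):
            _accum(self, _unbroadcast(g * other.data, self.shape))
            _accum(other, _unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data)
        _attach(out, (self, other))

        def bwd(g):
            _accum(self, _unbroadcast(g / other.data, self.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p)
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data))
        _attach(out, (self, other))

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
            elif b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim == 2 else g[..., None] * b
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
            if b.ndim == 1:
                gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else a * g
            elif a.ndim == 1:
                gb = np.multiply.outer(a, g)
            else:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            _accum(self, _unbroadcast(np.asarray(ga), self.shape))
            _accum(other, _unbroadcast(np.asarray(gb), other.shape))

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        _attach(out, (self,))

        def bwd(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.data))
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g / self.data)
        return out

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data))
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g * (1.0 - out.data**2))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g * (self.data > 0))
        return out

    def selu(self):
        x = self.data
        pos = x > 0
        out_data = SELU_SCALE * np.where(pos, x, SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))
        out = Tensor(out_data)
        _attach(out, (self,))

        def bwd(g):
            deriv = SELU_SCALE * np.where(pos, 1.0, SELU_ALPHA * np.exp(np.minimum(x, 0.0)))
            _accum(self, g * deriv)

        out._backward = bwd
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes))
        _attach(out, (self,))
        out._backward = lambda g: _accum(self, g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        _attach(out, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            _accum(self, full)

        out._backward = bwd
        return out


def _attach(out: Tensor, parents: tuple):
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents


def _accum(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- functional
def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    _attach(out, tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col.

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,).  Returns (B, O, Ho, Wo).
    """
    B, C, H, W = x.shape
    O, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C} vs kernel {C2}")
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xd.shape[2], xd.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1

    # im2col index grids
    i0 = np.repeat(np.arange(kh), kw)
    j0 = np.tile(np.arange(kw), kh)
    i1 = stride * np.repeat(np.arange(Ho), Wo)
    j1 = stride * np.tile(np.arange(Wo), Ho)
    ii = i0[:, None] + i1[None, :]          # (kh*kw, L)
    jj = j0[:, None] + j1[None, :]
    cols = xd[:, :, ii, jj]                 # (B, C, kh*kw, L)
    L = Ho * Wo
    cols2 = cols.reshape(B, C * kh * kw, L)

    wmat = w.data.reshape(O, C * kh * kw)
    out_data = np.matmul(wmat, cols2)       # (B, O, L)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    out = Tensor(out_data.reshape(B, O, Ho, Wo))
    parents = (x, w) if b is None else (x, w, b)
    _attach(out, parents)

    def bwd(g):
        gmat = g.reshape(B, O, L)
        gw = np.einsum("bol,bcl->oc", gmat, cols2).reshape(w.shape)
        _accum(w, gw)
        if b is not None:
            _accum(b, gmat.sum(axis=(0, 2)))
        gcols2 = np.matmul(wmat.T[None], gmat)          # (B, C*kh*kw, L)
        gcols = gcols2.reshape(B, C, kh * kw, L)
        gx = np.zeros((B, C, Hp, Wp))
        np.add.at(gx, (slice(None), slice(None), ii, jj), gcols)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        _accum(x, gx)

    out._backward = bwd
    return out
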