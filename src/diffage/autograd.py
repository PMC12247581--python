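"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the dual-guidance diffusion network needs:
broadcast arithmetic, matmul, 2D convolution (im2col), reductions, the usual
pointwise nonlinearities, concatenation and slicing.  Gradients are dense
float64 numpy arrays; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        """Matrix product; operands must be >= 2-D (batch dims broadcast)."""
        other = self._coerce(other)

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        orig_shape = self.shape

        def backward(g):
            out = np.zeros(orig_shape)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1 - out_data ** 2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def softmax(self, axis=-1):
        z = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backprop -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg
        # leaves reached through the loop above already accumulated into .grad


def concat(tensors, axis=0):
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Patch matrix of shape (n*ho*wo, kh*kw*c); NHWC keeps the copy fast."""
    n, h, w, c = x.shape
    if pad:
        xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
        xp[:, pad:-pad, pad:-pad, :] = x
        x = xp
    ho = (x.shape[1] - kh) // stride + 1
    wo = (x.shape[2] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, ho, wo, kh, kw, c), (s0, s1 * stride, s2 * stride, s1, s2, s3))
    return np.ascontiguousarray(cols).reshape(n * ho * wo, kh * kw * c), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution, NHWC layout; weight is (kh, kw, C_in, C_out)."""
    n, h, w, c = x.shape
    kh, kw, ci, co = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)   # (n*L, kh*kw*c)
    wmat = weight.data.reshape(kh * kw * ci, co)
    out = cols @ wmat                                         # (n*L, co)
    if bias is not None:
        out += bias.data
    out = out.reshape(n, ho, wo, co)

    def backward(g):
        gmat = np.ascontiguousarray(g).reshape(n * ho * wo, co)
        gw = (cols.T @ gmat).reshape(weight.shape)
        gcols = (gmat @ wmat.T).reshape(n, ho, wo, kh, kw, c)
        # col2im scatter-add
        hp, wp = h + 2 * padding, w + 2 * padding
        gx = np.zeros((n, hp, wp, c))
        for i in range(kh):
            for j in range(kw):
                gx[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :] += gcols[:, :, :, i, j, :]
        if padding:
            gx = gx[:, padding:-padding, padding:-padding, :]
        gb = None if bias is None else g.sum(axis=(0, 1, 2))
        return gx, gw, gb

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)
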