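"""Small neural-network building blocks on top of :mod:`diffage.autograd`.

The networks here are deliberately compact: the desk-scale profile trains a
width-reduced residual convolutional encoder on 32x32 slices on a single CPU.
Widths and depths are configurable so the same code scales up.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Module", "Linear", "Conv2d", "ResidualBlock", "ResNetEncoder",
    "MLP", "Adam", "sinusoidal_embedding",
]


class Module:
    """Base class; tracks parameters through attribute traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return Tensor(w, requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = _kaiming(rng, (n_in, n_out), n_in)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Convolution in NHWC layout; weight shape (k, k, c_in, c_out)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        self.weight = _kaiming(rng, (k, k, c_in, c_out), c_in * k * k)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ResidualBlock(Module):
    """conv-relu-conv with identity (or 1x1 projection) skip connection."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1):
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, stride=1, padding=1)
        self.proj = (Conv2d(c_in, c_out, 1, rng, stride=stride, padding=0, bias=False)
                     if (stride != 1 or c_in != c_out) else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        skip = x if self.proj is None else self.proj(x)
        return (h + skip).relu()


class ResNetEncoder(Module):
    """Residual convolutional encoder.

    ``widths`` gives the channel count per stage; each stage halves the
    spatial resolution.  ``feature_map`` returns the final H' x W' x C grid
    (used by the saliency stream); ``__call__`` adds global average pooling
    and a linear projection to ``embed_dim``.
    """

    def __init__(self, widths: tuple[int, ...], embed_dim: int,
                 rng: np.random.Generator, in_channels: int = 1,
                 stem_stride: int = 1):
        self.stem = Conv2d(in_channels, widths[0], 3, rng, stride=stem_stride,
                           padding=1)
        self.blocks = [ResidualBlock(widths[i - 1] if i else widths[0], w, rng, stride=2)
                       for i, w in enumerate(widths)]
        self.head = Linear(widths[-1], embed_dim, rng)
        self.out_channels = widths[-1]
        self.embed_dim = embed_dim

    def feature_map(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        for b in self.blocks:
            h = b(h)
        return h

    def __call__(self, x: Tensor) -> Tensor:
        h = self.feature_map(x)
        pooled = h.mean(axis=(1, 2))
        return self.head(pooled)


class MLP(Module):
    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Transformer-style sinusoidal embedding of (integer) timesteps."""
    t = np.asarray(t, dtype=np.float64).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], dim - emb.shape[1]))], axis=1)
    return emb
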