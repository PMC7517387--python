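"""Minimal NumPy CNN engine: layers, hand-written backprop, SGD.

Everything runs in float32 NCHW.  A forward pass records (op, inputs,
output) triples on a :class:`Tape`; ``Tape.backward`` walks the record in
reverse, accumulating gradients into parameter ``.grad`` buffers and
handling tensors consumed by several ops (e.g. an encoder feature map feeding
both the next stage and a skip connection).  Each layer instance must appear
at most once per forward pass, since it caches its forward activations.

Convolutions use stride 1 with same padding; downsampling happens only in
the dedicated 2×2/stride-2 max-pool, which records per-window argmax indices
(first position wins ties, row-major) for index-based unpooling in the
decoder.  Weight init is He-uniform from a seeded generator, so a fixed seed
reproduces a network bit-for-bit.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Tape", "Layer",
    "Conv2D", "ConvTranspose2x2", "BatchNorm2D", "LeakyReLU", "Sigmoid",
    "MaxPool2x2", "MaxUnpool2x2", "Concat", "Add",
    "SGD", "he_uniform",
]

DTYPE = np.float32


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Param:
    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)


class Tape:
    """Execution record of one forward pass, replayed in reverse for grads."""

    def __init__(self) -> None:
        self.ops: list[tuple["Layer", tuple[np.ndarray, ...], np.ndarray]] = []

    def apply(self, op: "Layer", *inputs: np.ndarray) -> np.ndarray:
        out = op.forward(*inputs)
        self.ops.append((op, inputs, out))
        return out

    def backward(self, output: np.ndarray, grad: np.ndarray) -> dict[int, np.ndarray]:
        grads: dict[int, np.ndarray] = {id(output): grad.astype(DTYPE)}
        for op, inputs, out in reversed(self.ops):
            g = grads.pop(id(out), None)
            if g is None:
                continue
            gins = op.backward(g)
            for x, gx in zip(inputs, gins):
                if gx is None:
                    continue
                if id(x) in grads:
                    grads[id(x)] = grads[id(x)] + gx
                else:
                    grads[id(x)] = gx
        return grads


class Layer:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, *xs: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> tuple[np.ndarray | None, ...]:  # pragma: no cover
        raise NotImplementedError


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 same-padding cross-correlation, NCHW input, (O,C,k,k) kernel.

    Implemented as k² shifted GEMMs ((O,C) @ (N,C,H·W)) on contiguous
    slices, which is far cheaper than an explicit im2col gather.
    """
    k = w.shape[2]
    N, C, H, W = x.shape
    O = w.shape[0]
    if k == 1:
        xf = x.reshape(N, C, H * W)
        y = np.matmul(w[:, :, 0, 0], xf)  # (N,O,HW)
        return y.reshape(N, O, H, W)
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    y = np.zeros((N, O, H * W), dtype=x.dtype)
    for u in range(k):
        for v in range(k):
            xs = np.ascontiguousarray(xp[:, :, u : u + H, v : v + W]).reshape(N, C, H * W)
            y += np.matmul(w[:, :, u, v], xs)
    return y.reshape(N, O, H, W)


class Conv2D(Layer):
    """k×k convolution, stride 1, same padding (odd k)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = in_ch * k * k
        self.W = Param(he_uniform(rng, (out_ch, in_ch, k, k), fan_in))
        self.b = Param(np.zeros(out_ch, dtype=DTYPE)) if bias else None
        self.k = k
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = _conv_same(x, self.W.value)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        x, k = self._x, self.k
        N, C, H, W = x.shape
        O = g.shape[1]
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2, 3))
        gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(O, N * H * W)
        if k == 1:
            xt = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(C, N * H * W)
            self.W.grad += (gt @ xt.T)[:, :, None, None]
            dx = np.matmul(self.W.value[:, :, 0, 0].T,
                           g.reshape(N, O, H * W)).reshape(N, C, H, W)
            return (dx,)
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        for u in range(k):
            for v in range(k):
                xt = np.ascontiguousarray(
                    xp[:, :, u : u + H, v : v + W].transpose(1, 0, 2, 3)
                ).reshape(C, N * H * W)
                self.W.grad[:, :, u, v] += gt @ xt.T
        # dx = correlation of g with the spatially flipped, io-transposed kernel
        wf = np.ascontiguousarray(self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx = _conv_same(g, wf)
        return (dx,)


class ConvTranspose2x2(Layer):
    """2×2 transpose convolution with stride 2 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.W = Param(he_uniform(rng, (in_ch, out_ch, 2, 2), in_ch))
        self.b = Param(np.zeros(out_ch, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        N, C, H, W = x.shape
        O = self.W.value.shape[1]
        y6 = np.einsum("nchw,couv->nohuwv", x, self.W.value, optimize=True)
        y = y6.reshape(N, O, 2 * H, 2 * W)
        y += self.b.value[None, :, None, None]
        return y

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        x = self._x
        N, C, H, W = x.shape
        O = g.shape[1]
        gb = g.reshape(N, O, H, 2, W, 2)
        self.b.grad += g.sum(axis=(0, 2, 3))
        self.W.grad += np.einsum("nchw,nohuwv->couv", x, gb, optimize=True)
        dx = np.einsum("nohuwv,couv->nchw", gb, self.W.value, optimize=True)
        return (dx,)


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch, dtype=DTYPE))
        self.beta = Param(np.zeros(ch, dtype=DTYPE))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean.astype(DTYPE)
            self.running_var = m * self.running_var + (1 - m) * var.astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(DTYPE)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        xhat, std = self._cache
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gs = self.gamma.value[None, :, None, None] / std[None, :, None, None]
        if not self.training:
            return (g * gs,)
        n = g.shape[0] * g.shape[2] * g.shape[3]
        mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
        dx = gs * (g - mean_g - xhat * mean_gx)
        return (dx.astype(DTYPE),)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = DTYPE(slope)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        # slope < 1, so leaky ReLU is exactly max(x, slope·x)
        return np.maximum(x, self.slope * x)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        out = g * self.slope
        np.copyto(out, g, where=self._mask)
        return (out,)


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # clipping at |x| = 40 keeps exp in range; sigmoid saturates there anyway
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))
        self._y = y
        return y

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        y = self._y
        return ((g * y * (1.0 - y)).astype(DTYPE),)


def max_pool_with_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2×2/stride-2 max pool; indices are row-major positions within each window.

    Ties resolve to the first (row-major) position.  H and W must be even.
    """
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"H and W must be even for 2x2 pooling, got {H}x{W}")
    win = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(N, C, H // 2, W // 2, 4)
    idx = win.argmax(axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(pooled), idx.astype(np.int8)


def unpool_with_indices(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Place each pooled value back at its recorded argmax; zeros elsewhere."""
    if x.shape != idx.shape:
        raise ValueError(f"value/index shape mismatch: {x.shape} vs {idx.shape}")
    N, C, Hh, Wh = x.shape
    win = np.zeros((N, C, Hh, Wh, 4), dtype=x.dtype)
    np.put_along_axis(win, idx.astype(np.intp)[..., None], x[..., None], axis=-1)
    out = win.reshape(N, C, Hh, Wh, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(out.reshape(N, C, 2 * Hh, 2 * Wh))


class MaxPool2x2(Layer):
    """Pooling layer; exposes the indices of its latest forward pass."""

    def __init__(self) -> None:
        self.indices: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pooled, self.indices = max_pool_with_indices(x)
        return pooled

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        return (unpool_with_indices(g, self.indices),)


class MaxUnpool2x2(Layer):
    """Index unpooling layer bound to a pooling layer's recorded indices."""

    def __init__(self, pool: MaxPool2x2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        return unpool_with_indices(x, self.pool.indices)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray]:
        N, C, H, W = g.shape
        win = g.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(N, C, H // 2, W // 2, 4)
        idx = self.pool.indices.astype(np.intp)[..., None]
        return (np.take_along_axis(win, idx, axis=-1)[..., 0],)


class Concat(Layer):
    """Channel-wise concatenation of any number of NCHW tensors."""

    def __init__(self) -> None:
        self._splits: list[int] = []

    def forward(self, *xs: np.ndarray) -> np.ndarray:
        self._splits = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, ...]:
        out, start = [], 0
        for c in self._splits:
            out.append(np.ascontiguousarray(g[:, start : start + c]))
            start += c
        return tuple(out)


class Add(Layer):
    """Elementwise sum of equally shaped tensors."""

    def __init__(self) -> None:
        self._n = 0

    def forward(self, *xs: np.ndarray) -> np.ndarray:
        self._n = len(xs)
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, ...]:
        return (g,) * self._n


class SGD:
    """Plain SGD with optional momentum over a list of Params."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p in self.params:
            if self.momentum:
                p.velocity = self.momentum * p.velocity - self.lr * p.grad
                p.value += p.velocity
            else:
                p.value -= self.lr * p.grad
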