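"""Minimal CNN training stack (numpy, CPU).

Implements exactly the layer vocabulary the sweep-detection architectures
need -- valid 2-D convolution, ReLU, 2x2 max pooling, row averaging,
flatten, dense, sigmoid -- with reverse-mode gradients, the Adam optimizer,
binary cross-entropy loss and elementwise L1+L2 weight penalties.

Conventions: activations are float32 arrays shaped ``(batch, height,
width, channels)``; convolutions are "valid" (no padding) with stride 1;
pooling is 2x2 with stride 2.  Convolutions are evaluated as im2col matrix
products chunked to bound peak memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2x2",
    "MeanOverRows",
    "Flatten",
    "Dense",
    "Sigmoid",
    "Network",
    "Adam",
    "bce_loss",
]

_CHUNK_BYTES = 192 * 1024 * 1024  # im2col chunk buffer cap
_COLS_CACHE_BYTES = 1300 * 1024 * 1024  # full patch-matrix cache cap


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _standard_normal(rng: np.random.Generator, shape, fan_in, fan_out):
    return rng.standard_normal(size=shape).astype(np.float32)


_INITIALIZERS = {"glorot_uniform": _glorot_uniform, "standard_normal": _standard_normal}


class Layer:
    """Base layer; stateless layers only implement forward/backward."""

    def init_params(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray, bool]]:
        """(name, value, gradient, regularized) tuples."""
        return []

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError


# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, out: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B * OH * OW, kh * kw * C) patch matrix.

    Built by kh*kw block copies of shifted slices into a caller-provided
    (reused) buffer; repeated fresh allocation of buffers this large is
    page-fault bound and dominates the convolution cost otherwise.
    """
    b, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    view = out.reshape(b, oh, ow, kh * kw * c)
    k = 0
    for i in range(kh):
        for j in range(kw):
            view[..., k : k + c] = x[:, i : i + oh, j : j + ow, :]
            k += c
    return out.reshape(b * oh * ow, kh * kw * c)


class _BufferPool:
    """Reusable named scratch arrays keyed by shape."""

    def __init__(self) -> None:
        self._store: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
        buf = self._store.get(name)
        size = int(np.prod(shape))
        if buf is None or buf.size < size:
            buf = np.empty(size, dtype=dtype)
            self._store[name] = buf
        return buf[:size].reshape(shape)


class Conv2D(Layer):
    def __init__(self, out_channels: int, kernel: tuple[int, int], init: str = "standard_normal",
                 regularize: bool = True):
        self.out_channels = out_channels
        self.kh, self.kw = kernel
        self.init = init
        self.regularize = regularize
        self.in_channels: int | None = None
        self.w: np.ndarray | None = None  # (kh*kw*cin, cout)
        self.b: np.ndarray | None = None
        self.dw: np.ndarray | None = None
        self.db: np.ndarray | None = None
        self._x: np.ndarray | None = None
        self._pool = _BufferPool()

    def build(self, in_shape):
        _, _, c = in_shape
        self.in_channels = c
        self._fan_in = self.kh * self.kw * c
        self._fan_out = self.kh * self.kw * self.out_channels

    def init_params(self, rng):
        fn = _INITIALIZERS[self.init]
        self.w = fn(rng, (self._fan_in, self.out_channels), self._fan_in, self._fan_out)
        self.b = np.zeros(self.out_channels, dtype=np.float32)

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        if h < self.kh or w < self.kw:
            raise ValueError(
                f"input {in_shape} too small for {self.kh}x{self.kw} convolution"
            )
        return (h - self.kh + 1, w - self.kw + 1, self.out_channels)

    def _chunk(self, b: int, oh: int, ow: int) -> int:
        rows_per_img = oh * ow
        bytes_per_img = rows_per_img * self._fan_in * 4
        return max(1, min(b, _CHUNK_BYTES // max(bytes_per_img, 1)))

    def forward(self, x):
        self._x = x
        b, h, w, _ = x.shape
        oh, ow = h - self.kh + 1, w - self.kw + 1
        out = self._pool.get("out", (b, oh, ow, self.out_channels))
        step = self._chunk(b, oh, ow)
        # keep the whole patch matrix when affordable so backward can skip
        # rebuilding it for the weight gradient
        total_bytes = b * oh * ow * self._fan_in * 4
        self._cols_cached = total_bytes <= _COLS_CACHE_BYTES
        colbuf = self._pool.get(
            "cols",
            ((b if self._cols_cached else min(step, b)) * oh * ow, self._fan_in),
        )
        for i in range(0, b, step):
            n = min(step, b - i)
            dst = colbuf[i * oh * ow : (i + n) * oh * ow] if self._cols_cached else colbuf[: n * oh * ow]
            cols = _im2col(x[i : i + n], self.kh, self.kw, dst)
            view = out[i : i + n].reshape(n * oh * ow, self.out_channels)
            np.matmul(cols, self.w, out=view)
            view += self.b
        return out

    def backward(self, dy, need_dx: bool = True):
        x = self._x
        b, h, w, c = x.shape
        oh, ow = dy.shape[1], dy.shape[2]
        self.dw = np.zeros_like(self.w)
        self.db = dy.sum(axis=(0, 1, 2))
        if getattr(self, "_cols_cached", False):
            cols = self._pool.get("cols", (b * oh * ow, self._fan_in))
            self.dw = cols.T @ dy.reshape(-1, self.out_channels)
        else:
            step = self._chunk(b, oh, ow)
            colbuf = self._pool.get("cols", (min(step, b) * oh * ow, self._fan_in))
            for i in range(0, b, step):
                n = min(step, b - i)
                cols = _im2col(x[i : i + n], self.kh, self.kw, colbuf[: n * oh * ow])
                dy_mat = dy[i : i + n].reshape(-1, self.out_channels)
                self.dw += cols.T @ dy_mat
        if not need_dx:
            return None
        # input gradient: full correlation of dy with the flipped kernel
        ph, pw = oh + 2 * (self.kh - 1), ow + 2 * (self.kw - 1)
        dy_p = self._pool.get("dy_pad", (b, ph, pw, self.out_channels))
        dy_p[:] = 0
        dy_p[:, self.kh - 1 : self.kh - 1 + oh, self.kw - 1 : self.kw - 1 + ow] = dy
        # (kh*kw*cout, cin) kernel for the transposed convolution
        w_r = (
            self.w.reshape(self.kh, self.kw, self.in_channels, self.out_channels)[::-1, ::-1]
            .transpose(0, 1, 3, 2)
            .reshape(self.kh * self.kw * self.out_channels, self.in_channels)
        )
        dx = self._pool.get("dx", x.shape)
        k2 = self.kh * self.kw * self.out_channels
        step2 = max(1, min(b, _CHUNK_BYTES // max(h * w * k2 * 4, 1)))
        colbuf2 = self._pool.get("cols2", (min(step2, b) * h * w, k2))
        for i in range(0, b, step2):
            n = min(step2, b - i)
            cols = _im2col(dy_p[i : i + n], self.kh, self.kw, colbuf2[: n * h * w])
            np.matmul(cols, w_r, out=dx[i : i + n].reshape(n * h * w, self.in_channels))
        return dx

    def params(self):
        return [("w", self.w, self.dw, True), ("b", self.b, self.db, False)]


class ReLU(Layer):
    """Rectifier applied in place (activations are layer-owned buffers)."""

    def __init__(self):
        self._pool = _BufferPool()

    def forward(self, x):
        self._mask = self._pool.get("mask", x.shape, dtype=bool)
        np.greater(x, 0, out=self._mask)
        np.maximum(x, 0, out=x)
        return x

    def backward(self, dy):
        dy *= self._mask  # dy buffers are writable within a step
        return dy

    def out_shape(self, in_shape):
        return in_shape


class MaxPool2x2(Layer):
    def __init__(self):
        self._pool = _BufferPool()

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if h < 2 or w < 2:
            raise ValueError("input too small for 2x2 pooling")
        return (h // 2, w // 2, c)

    def forward(self, x):
        b, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        self._x = x
        quads = (
            x[:, 0 : oh * 2 : 2, 0 : ow * 2 : 2],
            x[:, 1 : oh * 2 : 2, 0 : ow * 2 : 2],
            x[:, 0 : oh * 2 : 2, 1 : ow * 2 : 2],
            x[:, 1 : oh * 2 : 2, 1 : ow * 2 : 2],
        )
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        self._out = out
        return out

    def backward(self, dy):
        b, h, w, c = self._in_shape
        oh, ow = h // 2, w // 2
        x, out = self._x, self._out
        dx = self._pool.get("dx", (b, h, w, c))
        dx[:] = 0
        remaining = self._pool.get("rem", out.shape, dtype=bool)
        remaining[:] = True  # first matching cell wins
        mask = self._pool.get("mask", out.shape, dtype=bool)
        tmp = self._pool.get("tmp", out.shape)
        for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
            quad = x[:, di : oh * 2 : 2, dj : ow * 2 : 2]
            np.equal(quad, out, out=mask)
            mask &= remaining
            np.multiply(dy, mask, out=tmp)
            dx[:, di : oh * 2 : 2, dj : ow * 2 : 2] = tmp
            np.logical_not(mask, out=mask)
            remaining &= mask
        return dx


class MeanOverRows(Layer):
    """Average across the haplotype (height) axis; the permutation-invariant
    pooling of the DeepSet architecture."""

    def __init__(self):
        self._pool = _BufferPool()

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (1, w, c)

    def forward(self, x):
        self._h = x.shape[1]
        return x.mean(axis=1, keepdims=True)

    def backward(self, dy):
        b, _, w, c = dy.shape
        out = self._pool.get("dx", (b, self._h, w, c))
        np.copyto(out, dy / self._h)  # broadcast over rows
        return out


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, units: int, init: str = "glorot_uniform", regularize: bool = True):
        self.units = units
        self.init = init
        self.regularize = regularize
        self.w = self.b = self.dw = self.db = None

    def build(self, in_shape):
        (self.in_features,) = in_shape

    def init_params(self, rng):
        fn = _INITIALIZERS[self.init]
        self.w = fn(rng, (self.in_features, self.units), self.in_features, self.units)
        self.b = np.zeros(self.units, dtype=np.float32)

    def out_shape(self, in_shape):
        return (self.units,)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, self.dw, self.regularize), ("b", self.b, self.db, False)]


class Sigmoid(Layer):
    def forward(self, x):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)

    def out_shape(self, in_shape):
        return in_shape


# ---------------------------------------------------------------------------


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Adam:
    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params: Sequence[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for i, (value, grad) in enumerate(params):
            m = self.m.setdefault(i, np.zeros_like(value))
            v = self.v.setdefault(i, np.zeros_like(value))
            m += (1 - b1) * (grad - m)
            v += (1 - b2) * (grad * grad - v)
            value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class Network:
    """An ordered stack of layers ending in a Sigmoid over one unit."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int],
                 l1: float = 0.0, l2: float = 0.0):
        self.layers = layers
        self.input_shape = input_shape
        self.l1, self.l2 = l1, l2
        shape = input_shape
        for layer in layers:
            if hasattr(layer, "build"):
                layer.build(shape)
            shape = layer.out_shape(shape)
        self.output_shape = shape

    # -- parameters ---------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init_params(rng)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray, bool]]:
        out = []
        for layer in self.layers:
            for _, value, grad, reg in layer.params():
                out.append((value, grad, reg))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [value.copy() for layer in self.layers for _, value, _, _ in layer.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [(layer, name) for layer in self.layers for name, _, _, _ in layer.params()]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for (layer, name), w in zip(flat, weights):
            current = getattr(layer, name if name in ("w", "b") else name)
            if current.shape != w.shape:
                raise ValueError("weight shape mismatch")
            setattr(layer, name, np.asarray(w, dtype=np.float32).copy())

    def param_count(self) -> int:
        return int(sum(v.size for v, _, _ in self.parameters()))

    def regularization_loss(self) -> float:
        total = 0.0
        for value, _, reg in self.parameters():
            if reg:
                total += self.l1 * np.abs(value).sum() + self.l2 * np.square(value).sum()
        return float(total)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        if out.ndim == 3:
            out = out[..., None]
        for layer in self.layers:
            out = layer.forward(out)
        return out.reshape(-1)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.array([])

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        p = self.forward(x)
        loss = bce_loss(p, y) + self.regularization_loss()
        if not isinstance(self.layers[-1], Sigmoid):
            raise ValueError("network must end with a sigmoid")
        # fused sigmoid + BCE gradient on the logit
        dz = ((p - y) / len(y)).astype(np.float32).reshape(-1, *self.output_shape)
        grad = dz
        for i, layer in enumerate(reversed(self.layers[:-1])):
            if i == len(self.layers) - 2 and isinstance(layer, Conv2D):
                layer.backward(grad, need_dx=False)  # input gradient unused
            else:
                grad = layer.backward(grad)
        updates = []
        for value, g, reg in self.parameters():
            if reg and (self.l1 or self.l2):
                g = g + self.l1 * np.sign(value) + 2 * self.l2 * value
            updates.append((value, g))
        optimizer.step(updates)
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        p = self.predict(x, batch_size=batch_size)
        return bce_loss(p, np.asarray(y, dtype=np.float32)) + self.regularization_loss()

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the sigmoid score with respect to each input pixel."""
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 3
        p = self.forward(x)
        grad = (p * (1 - p)).astype(np.float32).reshape(-1, *self.output_shape)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        grad = grad.copy()  # detach from the layer's reusable buffer
        return grad[..., 0] if squeeze or grad.shape[-1] == 1 else grad
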