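"""Minimal CNN engine: layers, backprop and the SGD optimizer.

Implements exactly the operations the screening architecture needs — 3x3
same-padding convolution (im2col + BLAS matmul), 2x2 max-pooling with floor
semantics on odd sizes, inverted dropout, dense layers, softmax
cross-entropy — plus stochastic gradient descent with Nesterov momentum and
the classic 1/(1 + decay * iteration) learning-rate decay. Data layout is
NHWC, float32 throughout. All randomness (weight init, dropout masks,
shuffling) flows through explicit numpy Generators, so training is bit-for-bit
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: forward caches what backward needs; params yields (array, grad)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Same-padding patch matrix: (N*H*W, kh*kw*C) from NHWC input.

    Patch columns are ordered (kh, kw, channel) so the innermost axis of the
    gather is contiguous in memory.
    """
    n, h, w, c = x.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, kh * kw * c)


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution with optional ReLU."""

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        relu: bool = True,
        input_layer: bool = False,
    ):
        kh, kw = kernel
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        self.relu = relu
        self.input_layer = input_layer  # skip the (unused) input gradient
        fan_in = kh * kw * in_channels
        self.w = glorot_uniform(rng, (fan_in, filters), fan_in, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = None  # gradients materialize on the first backward pass
        self.db = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        cols = _im2col(x, *self.kernel)
        out = cols @ self.w + self.b
        self._cols = cols if train else None
        n, h, w, _ = x.shape
        out = out.reshape(n, h, w, self.filters)
        if self.relu:
            self._mask = out > 0
            out = np.maximum(out, 0.0, out=out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        n, h, w, f = dout.shape
        dflat = dout.reshape(n * h * w, f)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        self._cols = None
        if self.input_layer:
            return np.empty(0, dtype=dout.dtype)
        # dx is the same-padding convolution of dout with the spatially flipped,
        # channel-transposed kernel.
        kh, kw = self.kernel
        wk = self.w.reshape(kh, kw, self.in_channels, f)
        wk_flip = np.ascontiguousarray(
            wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(kh * kw * f, self.in_channels)
        )
        dx = _im2col(dout, kh, kw) @ wk_flip
        return dx.reshape(self._shape)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def weights_hwcf(self) -> np.ndarray:
        """Kernel weights as (kh, kw, in_channels, filters)."""
        kh, kw = self.kernel
        return self.w.reshape(kh, kw, self.in_channels, self.filters)


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2; odd trailing rows/columns are dropped (floor)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : h2 * 2, : w2 * 2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h2, w2, 4, c)
        self._argmax = win.argmax(axis=3) if train else None
        return win.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dout.shape
        dwin = np.zeros((n, h2, w2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : h2 * 2, : w2 * 2, :] = (
            dwin.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, relu: bool = True):
        self.relu = relu
        self.w = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dw = None  # gradients materialize on the first backward pass
        self.db = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        out = x @ self.w + self.b
        if self.relu:
            self._mask = out > 0
            out = np.maximum(out, 0.0, out=out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-(onehot * np.log(probs + eps)).sum() / n)
    grad = (probs - onehot) / n
    return loss, grad.astype(logits.dtype)


class SGD:
    """Stochastic gradient descent with Nesterov momentum and 1/(1+decay*t) lr decay.

    ``clipnorm`` rescales each step's gradients so their global L2 norm never
    exceeds the bound — a numerical safeguard against the rare late-training
    gradient spikes of a momentum optimizer on a confidently-fit network; it is
    inactive whenever gradients are moderate and ``None`` disables it.
    """

    def __init__(
        self,
        params_fn,
        learning_rate: float = 0.01,
        decay: float = 1e-6,
        momentum: float = 0.9,
        nesterov: bool = True,
        clipnorm: float | None = 5.0,
    ):
        # params_fn() -> current [(param, grad)] pairs; gradients are rebound
        # by each backward pass, so they are fetched fresh every step.
        self.params_fn = params_fn
        self.lr = learning_rate
        self.decay = decay
        self.momentum = momentum
        self.nesterov = nesterov
        self.clipnorm = clipnorm
        self.iterations = 0
        self.velocity = [np.zeros_like(p) for p, _ in params_fn()]

    def step(self) -> None:
        params = self.params_fn()
        lr_t = self.lr / (1.0 + self.decay * self.iterations)
        if self.clipnorm is not None:
            global_norm = np.sqrt(sum(float(np.sum(g * g)) for _, g in params))
            if global_norm > self.clipnorm:
                scale = self.clipnorm / global_norm
                for _, g in params:
                    g *= scale
        for (p, g), v in zip(params, self.velocity):
            v *= self.momentum
            v -= lr_t * g
            if self.nesterov:
                p += self.momentum * v - lr_t * g
            else:
                p += v
        self.iterations += 1
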