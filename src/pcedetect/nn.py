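"""Minimal numpy neural-network layers with explicit backpropagation.

Only what the two detectors need: 1D (transposed) convolutions, dense
layers, ReLU/PReLU, dropout, max-pooling, softmax heads with categorical
cross-entropy and generalized dice losses, and Adam.  Shapes are
(batch, length, channels) throughout; gradients accumulate into
``Param.grad`` and every backward pass is covered by finite-difference
tests.  Single-threaded numpy makes training bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1D(Layer):
    """1D convolution over (B, L, Cin) -> (B, Lout, Cout).

    ``padding='same'`` keeps the length (stride 1 only); ``'valid'`` crops.
    Strided valid convolution with kernel == stride implements the V-Net
    down-sampling convs exactly.
    """

    def __init__(self, cin: int, cout: int, kernel: int, *, stride: int = 1,
                 padding: str = "valid", rng: np.random.Generator,
                 name: str = "conv") -> None:
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and stride != 1:
            raise ValueError("'same' padding requires stride 1")
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.padding = padding
        self.W = Param(_he_init(rng, (kernel * cin, cout), kernel * cin),
                       f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        if self.padding == "same":
            left = (self.k - 1) // 2
            right = self.k - 1 - left
            return np.pad(x, ((0, 0), (left, right), (0, 0))), left
        return x, 0

    def forward(self, x, *, training=False, rng=None):
        xp, _ = self._pad(x)
        B, Lp, _ = xp.shape
        lout = (Lp - self.k) // self.stride + 1
        if lout < 1:
            raise ValueError(
                f"input length {x.shape[1]} too short for kernel {self.k}")
        cols = np.empty((B, lout, self.k, self.cin))
        for j in range(self.k):
            cols[:, :, j, :] = xp[:, j:j + lout * self.stride:self.stride, :]
        self._cols = cols.reshape(B, lout, self.k * self.cin)
        self._xshape = x.shape
        return self._cols @ self.W.value + self.b.value

    def backward(self, gy):
        B, lout, _ = gy.shape
        self.W.grad += self._cols.reshape(-1, self.k * self.cin).T @ \
            gy.reshape(-1, self.cout)
        self.b.grad += gy.sum(axis=(0, 1))
        gcols = (gy @ self.W.value.T).reshape(B, lout, self.k, self.cin)
        Lp = self._xshape[1] + (self.k - 1 if self.padding == "same" else 0)
        gxp = np.zeros((B, Lp, self.cin))
        for j in range(self.k):
            gxp[:, j:j + lout * self.stride:self.stride, :] += gcols[:, :, j, :]
        if self.padding == "same":
            left = (self.k - 1) // 2
            return gxp[:, left:left + self._xshape[1], :]
        return gxp


class ConvTranspose1D(Layer):
    """Transposed 1D convolution with kernel == stride (exact upsampling)."""

    def __init__(self, cin: int, cout: int, *, kernel: int = 2, stride: int = 2,
                 rng: np.random.Generator, name: str = "convT") -> None:
        if kernel != stride:
            raise ValueError("only kernel == stride upsampling is supported")
        self.cin, self.cout, self.k = cin, cout, kernel
        self.W = Param(_he_init(rng, (cin, kernel, cout), cin), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        B, L, _ = x.shape
        y = np.einsum("blc,ckd->blkd", x, self.W.value)
        return y.reshape(B, L * self.k, self.cout) + self.b.value

    def backward(self, gy):
        B, Lk, _ = gy.shape
        g = gy.reshape(B, Lk // self.k, self.k, self.cout)
        self.W.grad += np.einsum("blc,blkd->ckd", self._x, g)
        self.b.grad += gy.sum(axis=(0, 1))
        return np.einsum("blkd,ckd->blc", g, self.W.value)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, *, rng: np.random.Generator,
                 name: str = "dense") -> None:
        self.W = Param(_he_init(rng, (nin, nout), nin), f"{name}.W")
        self.b = Param(np.zeros(nout), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.reshape(-1, self._x.shape[-1]).T @ \
            gy.reshape(-1, gy.shape[-1])
        self.b.grad += gy.reshape(-1, gy.shape[-1]).sum(axis=0)
        return gy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, gy):
        return gy * self._pos


class PReLU(Layer):
    """Parametric ReLU with one slope per channel (last axis)."""

    def __init__(self, channels: int, *, init: float = 0.25,
                 name: str = "prelu") -> None:
        self.alpha = Param(np.full(channels, init), f"{name}.alpha")

    def params(self) -> list[Param]:
        return [self.alpha]

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        self._neg = x < 0
        return np.where(self._neg, self.alpha.value * x, x)

    def backward(self, gy):
        g_neg = gy * self._x * self._neg
        self.alpha.grad += g_neg.reshape(-1, g_neg.shape[-1]).sum(axis=0)
        return np.where(self._neg, self.alpha.value * gy, gy)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis."""

    def __init__(self, pool: int = 2) -> None:
        self.pool = pool

    def forward(self, x, *, training=False, rng=None):
        B, L, C = x.shape
        if L % self.pool:
            raise ValueError(f"length {L} not divisible by pool {self.pool}")
        xr = x.reshape(B, L // self.pool, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._xshape = x.shape
        return xr.max(axis=2)

    def backward(self, gy):
        B, Lo, C = gy.shape
        gx = np.zeros((B, Lo, self.pool, C))
        bi, li, ci = np.ogrid[:B, :Lo, :C]
        gx[bi, li, self._arg, ci] = gy
        return gx.reshape(self._xshape)


class Flatten(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, *, training=False, rng=None):
        for l in self.layers:
            x = l.forward(x, training=training, rng=rng)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(labels, dtype=np.int64)]


def cross_entropy_with_softmax(logits: np.ndarray, onehot: np.ndarray
                               ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = int(np.prod(logits.shape[:-1]))
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    return loss, (p - onehot) / n


def generalized_dice_loss(probs: np.ndarray, onehot: np.ndarray,
                          eps: float = 1e-5) -> float:
    """Generalized dice loss with inverse-squared class-frequency weights.

        L = 1 - 2 * sum_c w_c sum_i p_ci g_ci / sum_c w_c sum_i (p_ci + g_ci)

    with w_c = 1 / (sum_i g_ci + eps)^2, summing i over every sample of the
    batch.  The inverse-squared weights make the rare class count as much
    as the background, which is what lets a segmentation net learn from
    ~2%-positive data.  Lies in [0, 1]: 0 for a perfect hard prediction,
    1 when the prediction is the complement of the truth.
    """
    p = probs.reshape(-1, probs.shape[-1])
    g = onehot.reshape(-1, onehot.shape[-1])
    w = 1.0 / (g.sum(axis=0) + eps) ** 2
    num = float((w * (p * g).sum(axis=0)).sum())
    den = float((w * (p + g).sum(axis=0)).sum())
    return 1.0 - 2.0 * num / den


def gdl_with_softmax(logits: np.ndarray, onehot: np.ndarray,
                     eps: float = 1e-5) -> tuple[float, np.ndarray]:
    """Generalized dice loss on softmax(logits) and its logit gradient."""
    p = softmax(logits)
    pf = p.reshape(-1, p.shape[-1])
    g = onehot.reshape(-1, onehot.shape[-1])
    w = 1.0 / (g.sum(axis=0) + eps) ** 2
    num = float((w * (pf * g).sum(axis=0)).sum())
    den = float((w * (pf + g).sum(axis=0)).sum())
    loss = 1.0 - 2.0 * num / den
    # dL/dp_ci = -2 (w_c g_ci den - num w_c) / den^2
    dp = -2.0 * (w * g * den - num * w) / den ** 2
    dp = dp.reshape(p.shape)
    # chain through softmax: dz = p * (dp - sum_c dp * p)
    dz = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
    return loss, dz
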