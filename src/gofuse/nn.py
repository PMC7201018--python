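"""A compact NumPy neural-network engine with hand-written backpropagation.

Provides exactly the layers the prediction models need — 1-D convolution
(im2col), max-pooling, ReLU, dense, embedding lookup and a binary-masked
dense layer — plus Adam and a numerically stable sigmoid/binary-cross-entropy
head. Arrays are float32 throughout; all parameter initialisation flows from
an explicit ``numpy.random.Generator`` so training runs are reproducible.

Conventions: convolutional inputs are (batch, channels, length); "same"-style
zero padding puts the extra element on the right for even kernels.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np

from .errors import ShapeError


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = "param"):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Uniform fan-in scaled init (gain for ReLU): U(-sqrt(6/fan_in), +)."""
    bound = float(np.sqrt(6.0 / max(fan_in, 1)))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    """Base layer: forward caches what backward needs; backward returns dX."""

    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int]:
    """Left/right zero padding so out_len = ceil(length / stride)."""
    out_len = -(-length // stride)
    total = max((out_len - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


class Conv1d(Layer):
    """1-D convolution over (batch, in_channels, length) with same-padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        self.weight = Parameter(
            kaiming_uniform(rng, (out_channels, in_channels, kernel), fan_in), "conv.weight"
        )
        self.bias = Parameter(np.zeros(out_channels), "conv.bias")

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ShapeError(
                f"conv1d expected (batch, {self.in_channels}, length), got {x.shape}"
            )
        b, c, length = x.shape
        pl, pr = _same_padding(length, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # windows: (b, c, out_len, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]
        out_len = win.shape[2]
        cols = win.transpose(0, 2, 1, 3).reshape(b, out_len, c * self.kernel)
        wmat = self.weight.value.reshape(self.out_channels, c * self.kernel)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape, (pl, pr), out_len)
        return y.transpose(0, 2, 1)  # (b, out_channels, out_len)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, (pl, pr), out_len = self._cache
        b, c, length = x_shape
        dyt = dy.transpose(0, 2, 1)  # (b, out_len, out_channels)
        wmat = self.weight.value.reshape(self.out_channels, c * self.kernel)
        self.weight.grad += (
            np.einsum("blo,blm->om", dyt, cols, optimize=True)
            .reshape(self.weight.value.shape)
        )
        self.bias.grad += dyt.sum(axis=(0, 1))
        dcols = dyt @ wmat  # (b, out_len, c*k)
        dcols = dcols.reshape(b, out_len, c, self.kernel).transpose(0, 2, 3, 1)
        dxp = np.zeros((b, c, length + pl + pr), dtype=np.float32)
        for t in range(self.kernel):
            dxp[:, :, t : t + self.stride * out_len : self.stride] += dcols[:, :, t, :]
        return dxp[:, :, pl : pl + length]


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel == stride); trailing remainder dropped."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, length = x.shape
        out_len = length // self.kernel
        xt = x[:, :, : out_len * self.kernel].reshape(b, c, out_len, self.kernel)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, length = self._in_shape
        out_len = length // self.kernel
        dx = np.zeros((b, c, out_len, self.kernel), dtype=np.float32)
        bi, ci, li = np.ogrid[:b, :c, :out_len]
        dx[bi, ci, li, self._argmax] = dy
        full = np.zeros((b, c, length), dtype=np.float32)
        full[:, :, : out_len * self.kernel] = dx.reshape(b, c, out_len * self.kernel)
        return full


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Linear(Layer):
    """Dense layer y = x W^T + b with weight (out_features, in_features)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            kaiming_uniform(rng, (out_features, in_features), in_features), "linear.weight"
        )
        self.bias = Parameter(np.zeros(out_features), "linear.bias")

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ShapeError(
                f"linear expected (batch, {self.in_features}), got {x.shape}"
            )
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class MaskedLinear(Layer):
    """Dense layer whose weight is elementwise-gated by a constant binary mask.

    The effective weight is ``W * mask`` in the forward pass, the gradient is
    gated by the same mask, and masked-out entries of ``W`` are pinned to
    exactly zero, so the sparsity pattern survives any number of optimizer
    steps bit-exactly.
    """

    def __init__(self, mask: np.ndarray, rng: np.random.Generator | None = None,
                 nonnegative_init: bool = False):
        rng = rng or np.random.default_rng(0)
        self.mask = np.asarray(mask, dtype=np.float32)
        out_features, in_features = self.mask.shape
        fan_in = max(int(self.mask.sum(axis=1).max()), 1)
        w = kaiming_uniform(rng, (out_features, in_features), fan_in)
        if nonnegative_init:
            # with nonnegative inputs (probabilities) a random-sign init can
            # start a ReLU unit permanently off; positive weights cannot
            w = np.abs(w)
        self.weight = Parameter(w * self.mask, "masked.weight")
        self.bias = Parameter(np.zeros(out_features), "masked.bias")

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def enforce_mask(self) -> None:
        self.weight.value *= self.mask

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.mask.shape[1]:
            raise ShapeError(
                f"masked linear expected (batch, {self.mask.shape[1]}), got {x.shape}"
            )
        self._x = x
        return x @ (self.weight.value * self.mask).T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += (dy.T @ self._x) * self.mask
        self.bias.grad += dy.sum(axis=0)
        return dy @ (self.weight.value * self.mask)


class Embedding(Layer):
    """Integer-index lookup table (vocab_size, dim); row 0 may be frozen zero.

    Freezing the padding row keeps padded sentence positions contributing
    exactly nothing to downstream convolutions.
    """

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator | None = None,
                 freeze_padding: bool = True):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, 1.0, size=(vocab_size, dim)).astype(np.float32)
        self.freeze_padding = freeze_padding
        if freeze_padding:
            w[0] = 0.0
        self.weight = Parameter(w, "embedding.weight")
        self.vocab_size = vocab_size
        self.dim = dim

    def parameters(self) -> List[Parameter]:
        return [self.weight]

    def forward(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx)
        if idx.min(initial=0) < 0 or idx.max(initial=0) >= self.vocab_size:
            raise ShapeError(
                f"embedding index outside [0, {self.vocab_size - 1}]"
            )
        self._idx = idx
        return self.weight.value[idx]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.add.at(self.weight.grad, self._idx, dy)
        if self.freeze_padding:
            self.weight.grad[0] = 0.0
        return np.zeros(self._idx.shape, dtype=np.float32)  # indices carry no gradient


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> List[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype) if z.dtype == np.float32 else out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dL/dz).

    Uses the log-sum-exp form, stable for any logit magnitude.
    """
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, dz


class Adam:
    """Adaptive moment estimation with bias correction (the field-standard
    defaults beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def state_dict(layers: Layer) -> Dict[str, np.ndarray]:
    """Ordered name->array snapshot of all parameters (deep copies)."""
    return {f"{i}:{p.name}": p.value.copy() for i, p in enumerate(layers.parameters())}


def load_state_dict(layers: Layer, state: Dict[str, np.ndarray]) -> None:
    params = layers.parameters()
    if len(params) != len(state):
        raise ShapeError(
            f"checkpoint has {len(state)} parameters, model has {len(params)}"
        )
    for (key, value), p in zip(state.items(), params):
        if p.value.shape != value.shape:
            raise ShapeError(
                f"parameter {key} shape {value.shape} != model shape {p.value.shape}"
            )
        p.value = np.asarray(value, dtype=np.float32).copy()
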