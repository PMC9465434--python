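"""A small convolutional network implemented on numpy.

The classifier used throughout the package is a plain block CNN — repeated
blocks of two 'same'-padded convolutions and a 2×2 max-pool, followed by
dense layers and a softmax output — trained with Adam on cross-entropy.
Forward and backward passes are written directly against numpy (im2col via
``sliding_window_view`` + ``einsum``), which keeps training fully
deterministic for a given seed and makes the gradients unit-testable
against finite differences.

Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ArchitectureSpec", "SmallCNN", "Adam", "softmax", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ArchitectureSpec:
    """Block-CNN architecture: each block is conv-conv-maxpool.

    The input side must survive ``n_blocks`` halvings, and the output layer
    width must match the label set (5 classes for error-type classification,
    2 for binary magnitude relevance, 10 for the joint variant).
    """

    n_blocks: int = 2
    filters_per_block: tuple[int, ...] = (8, 16)
    kernel_side: int = 3
    n_dense: int = 1
    dense_units: tuple[int, ...] = (64,)
    n_input_channels: int = 1
    n_classes: int = 5
    input_side: int = 64

    def __post_init__(self) -> None:
        self.filters_per_block = tuple(self.filters_per_block)
        self.dense_units = tuple(self.dense_units)
        if self.n_blocks < 1 or len(self.filters_per_block) != self.n_blocks:
            raise ValueError("need one filter count per block")
        if self.n_dense < 1 or len(self.dense_units) != self.n_dense:
            raise ValueError("need one width per dense layer")
        if self.kernel_side % 2 == 0 or self.kernel_side < 1:
            raise ValueError("kernel side must be odd")
        if not 1 <= self.n_input_channels <= 3:
            raise ValueError("1-3 input channels supported")
        if self.input_side % (2**self.n_blocks) != 0:
            raise ValueError("input side must be divisible by 2^n_blocks")
        if self.input_side // (2**self.n_blocks) < 1:
            raise ValueError("too many pooling stages for the input size")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def flat_features(self) -> int:
        side = self.input_side // (2**self.n_blocks)
        return side * side * self.filters_per_block[-1]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Conv:
    """'Same'-padded 2D convolution (correlation) layer."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k * k))  # He initialization
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k = k

    @staticmethod
    def _windows(x: np.ndarray, k: int) -> np.ndarray:
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        return sliding_window_view(xp, (k, k), axis=(2, 3))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._win = self._windows(x, self.k)
        return (
            np.einsum("nchwpq,fcpq->nfhw", self._win, self.W, optimize=True)
            + self.b[None, :, None, None]
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("nchwpq,nfhw->fcpq", self._win, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        dwin = self._windows(dout, self.k)
        w_flip = self.W[:, :, ::-1, ::-1]
        dx = np.einsum("nfhwpq,fcpq->nchw", dwin, w_flip, optimize=True)
        self._win = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # distribute gradient equally over tied maxima
        mask = xr == out[:, :, :, None, :, None]
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        return out

    def backward(self, dout):
        g = self._mask * dout[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = g.shape
        self._mask = None
        return g.reshape(n, c, h2 * 2, w2 * 2)

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class SmallCNN:
    """Block CNN with a softmax head; see :class:`ArchitectureSpec`."""

    def __init__(self, arch: ArchitectureSpec, rng: np.random.Generator | int = 0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.arch = arch
        self.layers: list = []
        in_ch = arch.n_input_channels
        for f in arch.filters_per_block:
            self.layers += [
                _Conv(in_ch, f, arch.kernel_side, rng),
                _ReLU(),
                _Conv(f, f, arch.kernel_side, rng),
                _ReLU(),
                _MaxPool2(),
            ]
            in_ch = f
        self.layers.append(_Flatten())
        n_in = arch.flat_features
        for u in arch.dense_units:
            self.layers += [_Dense(n_in, u, rng), _ReLU()]
            n_in = u
        self.layers.append(_Dense(n_in, arch.n_classes, rng))

    # -- forward / loss -------------------------------------------------
    def logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.logits(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty((0, self.arch.n_classes))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        """Mean cross-entropy without touching layer caches beyond forward."""
        total = 0.0
        for i in range(0, len(x), batch_size):
            p = softmax(self.logits(x[i : i + batch_size]))
            total += -np.log(
                np.maximum(p[np.arange(len(y[i : i + batch_size])), y[i : i + batch_size]], 1e-12)
            ).sum()
        return total / len(x)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward+backward pass; gradients stored on the layers."""
        logits = self.logits(x)
        p = softmax(logits)
        n = len(x)
        loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss

    # -- parameter access ------------------------------------------------
    def parameters(self) -> list[tuple[str, object]]:
        return [p for layer in self.layers for p in layer.params()]

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(holder, name).copy() for name, holder in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (name, holder), w in zip(self.parameters(), weights):
            setattr(holder, name, w.copy())


class Adam:
    """Adam optimizer over a :class:`SmallCNN`'s parameters."""

    def __init__(self, model: SmallCNN, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(h, n)) for n, h in model.parameters()]
        self.v = [np.zeros_like(getattr(h, n)) for n, h in model.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (name, holder) in enumerate(self.model.parameters()):
            g = getattr(holder, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p = getattr(holder, name)
            setattr(holder, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
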