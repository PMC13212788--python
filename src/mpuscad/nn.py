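"""Minimal dense/3D-convolutional neural-network engine on numpy.

Implements exactly what the voxel classifier needs — valid-mode 3D
convolutions, ReLU, fully connected layers, a numerically stable weighted
binary cross-entropy on logits, and the Adam optimizer — with analytic
backpropagation.  Everything is deterministic given the seed and runs on a
single CPU core; the classifier totals ~47k parameters, so no GPU framework
is required.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv3d", "ReLU", "Flatten", "Dense", "Sequential",
    "Adam", "sigmoid", "weighted_bce_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    trainable = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


DTYPE = np.float32  # training dtype; float32 halves the memory-bound gathers


class Conv3d(Layer):
    """Valid-mode 3D convolution on (N, C, D, H, W) batches, kernel k^3."""

    def __init__(self, in_c: int, out_c: int, k: int = 3,
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng or np.random.default_rng()
        fan_in = in_c * k**3
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU nonlinearity
        self.k = k
        self.in_c = in_c
        self.out_c = out_c
        self.W = Param(rng.normal(0.0, scale, size=(out_c, in_c, k, k, k)).astype(dtype))
        self.b = Param(np.zeros(out_c, dtype=dtype))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        self._xshape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        win = np.moveaxis(win, 1, 4)  # (N, Do, Ho, Wo, C, k, k, k)
        n, do, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win).reshape(n * do * ho * wo, -1)
        self._cols = cols
        self._out_sp = (do, ho, wo)
        y = cols @ self.W.value.reshape(self.out_c, -1).T + self.b.value
        return np.moveaxis(y.reshape(n, do, ho, wo, self.out_c), -1, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        n = grad.shape[0]
        do, ho, wo = self._out_sp
        g2 = np.moveaxis(grad, 1, -1).reshape(-1, self.out_c)
        self.W.grad += (g2.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.reshape(self.out_c, -1)).reshape(
            n, do, ho, wo, self.in_c, k, k, k
        )
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dx[:, :, i:i + do, j:j + ho, l:l + wo] += np.moveaxis(
                        dcols[..., i, j, l], -1, 1
                    )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 dtype=DTYPE):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_f)
        self.W = Param(rng.normal(0.0, scale, size=(in_f, out_f)).astype(dtype))
        self.b = Param(np.zeros(out_f, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam without weight decay (training uses no weight regularization)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_bce_logits(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Confidence-weighted binary cross-entropy on logits.

    loss = sum_i w_i * (softplus(z_i) - y_i z_i) / sum_i w_i, the stable form
    of -sum w [y log p + (1-y) log(1-p)] / sum w; returns (loss, dloss/dz).
    """
    z = logits.ravel().astype(np.float64)
    y = labels.ravel().astype(np.float64)
    w = weights.ravel().astype(np.float64)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = w.sum()
    softplus = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))
    loss = float(np.sum(w * (softplus - y * z)) / sw)
    dz = (w * (sigmoid(z) - y) / sw).reshape(logits.shape).astype(logits.dtype)
    return loss, dz
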