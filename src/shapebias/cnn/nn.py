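"""Minimal feed-forward network building blocks in numpy.

Convolutions use im2col (``sliding_window_view`` + one matmul); the
backward pass scatters gradients back with a small loop over kernel
offsets.  Everything is deterministic given the numpy Generator used for
initialisation and batching.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A weight tensor with its gradient and a freeze flag."""

    __slots__ = ("value", "grad", "frozen", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.frozen = False
        self.name = name


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style convolution with zero padding and stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, fan_in)).astype(np.float32)
        self.w = Parameter(w, "conv_w")
        self.b = Parameter(np.zeros(out_ch, dtype=np.float32), "conv_b")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                      # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, (oh, ow))
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (oh, ow) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.w.grad[...] = g.T @ cols
        self.b.grad[...] = g.sum(axis=0)
        dcols = (g @ self.w.value).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # split gradient between ties so it never double-counts
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim),
                       size=(out_dim, in_dim)).astype(np.float32)
        self.w = Parameter(w, "linear_w")
        self.b = Parameter(np.zeros(out_dim, dtype=np.float32), "linear_b")

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad[...] = grad.T @ self._x
        self.b.grad[...] = grad.sum(axis=0)
        return grad @ self.w.value


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def checksum(self) -> float:
        """Cheap fingerprint of all parameter values (frozen-weight checks)."""
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``targets`` are 0-based integer class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = len(targets)
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimiser; frozen parameters are skipped entirely."""

    def __init__(self, params: list[Parameter], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.frozen:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
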