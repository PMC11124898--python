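"""Minimal 1-D convolutional network engine (numpy, full-batch SGD).

The networks used here are tiny (two conv layers and a two-layer
perceptron, a few thousand to ~10^5 parameters, a few hundred training
samples), so a vectorized numpy implementation with explicit
backpropagation is fast and — crucially for reproducibility contracts —
bit-for-bit deterministic given a seed.

Layers operate on arrays shaped (N, C, L); gradients flow through
``backward`` in reverse layer order. Weights are Gaussian-initialized
with He scaling (std = sqrt(2 / fan_in)), appropriate for ReLU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ReLU", "Flatten", "Dense", "Sequential",
           "softmax", "train_network", "conv_output_length", "DTYPE"]

# single precision is plenty for these shallow networks and halves the
# memory traffic of the matmuls; float64 remains available for gradient
# verification
DTYPE = np.float32


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Output length of a valid (no padding) strided 1-D convolution."""
    if length < kernel:
        return 0
    return (length - kernel) // stride + 1


class Conv1d:
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=None):
        dtype = dtype or DTYPE
        fan_in = in_ch * kernel
        self.W = rng.normal(scale=np.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, kernel)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.stride = stride
        self.kernel = kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        # im2col: gather strided windows into a contiguous (N*Lo, C*K)
        # matrix so both passes are single BLAS matmuls
        k, s = self.kernel, self.stride
        n, c, length = x.shape
        lo = conv_output_length(length, k, s)
        if lo < 1:
            raise ValueError(f"input length {length} too short for kernel {k}")
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::s, :]
        col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * lo, c * k)
        self._x_shape, self._col, self._lo = x.shape, col, lo
        out = col @ self.W.reshape(self.W.shape[0], -1).T
        return out.reshape(n, lo, -1).transpose(0, 2, 1) + self.b[None, :, None]

    def backward(self, go: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, length = self._x_shape
        o, lo = go.shape[1], self._lo
        gor = np.ascontiguousarray(go.transpose(0, 2, 1)).reshape(n * lo, o)
        self.dW = (gor.T @ self._col).reshape(self.W.shape)
        self.db = go.sum(axis=(0, 2))
        gcol = (gor @ self.W.reshape(o, -1)).reshape(n, lo, c, k)
        dx = np.zeros(self._x_shape, dtype=gcol.dtype)
        idx = np.arange(lo) * s
        for j in range(k):
            dx[:, :, idx + j] += gcol[:, :, :, j].transpose(0, 2, 1)
        return dx

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=None):
        dtype = dtype or DTYPE
        self.W = rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, go: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ go
        self.db = go.sum(axis=0)
        return go @ self.W.T

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, go: np.ndarray) -> np.ndarray:
        return go * self._mask

    @property
    def params(self):
        return []

    def grads(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, go: np.ndarray) -> np.ndarray:
        return go.reshape(self._shape)

    @property
    def params(self):
        return []

    def grads(self):
        return []


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, go: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            go = layer.backward(go)
        return go

    def parameters(self):
        return [p for layer in self.layers for _, p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_network(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float = 0.001,
    decay: float = 0.9,
    decay_mode: str = "momentum",
) -> list[float]:
    """Full-batch gradient descent on softmax cross-entropy.

    ``decay`` is interpreted per ``decay_mode``: the momentum coefficient
    of SGD (default), or a per-epoch multiplicative learning-rate decay.
    Returns the per-epoch loss trajectory.
    """
    if decay_mode not in ("momentum", "lr_decay"):
        raise ValueError(f"unknown decay_mode {decay_mode!r}")
    n = X.shape[0]
    X = np.ascontiguousarray(X, dtype=net.parameters()[0].dtype)
    onehot = np.zeros((n, 3), dtype=X.dtype)
    onehot[np.arange(n), y] = 1.0
    velocity = [np.zeros_like(p) for p in net.parameters()]
    losses = []
    step_lr = lr
    for epoch in range(epochs):
        probs = softmax(net.forward(X))
        loss = -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1))
        losses.append(float(loss))
        net.backward((probs - onehot) / n)
        if decay_mode == "momentum":
            for v, p, g in zip(velocity, net.parameters(), net.gradients()):
                v *= decay
                v -= lr * g
                p += v
        else:
            for p, g in zip(net.parameters(), net.gradients()):
                p -= step_lr * g
            step_lr *= decay
    return losses
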