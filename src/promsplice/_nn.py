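"""Minimal feed-forward / 1-D convolutional network core (numpy, CPU).

Supports exactly what the classifiers here need: dense layers, ReLU, inverted
dropout, 1-D convolution over the promoter axis with TFs as channels, max
pooling, a sigmoid output with binary cross-entropy, and Adam.  Training is
deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv1D:
    """Valid-mode 1-D convolution; input (batch, length, channels)."""

    def __init__(self, n_channels: int, n_filters: int, kernel: int,
                 rng: np.random.Generator):
        fan_in = kernel * n_channels
        limit = np.sqrt(6.0 / (fan_in + n_filters))
        self.W = rng.uniform(-limit, limit, (kernel, n_channels, n_filters)).astype(
            np.float32
        )
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.kernel = kernel

    @property
    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        # (batch, out_len, kernel, channels) view, then fold for one GEMM
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (batch, out_len, channels, kernel) -> (batch, out_len, kernel*channels)
        win = win.transpose(0, 1, 3, 2)
        return np.ascontiguousarray(win).reshape(x.shape[0], -1, self.kernel * x.shape[2])

    def forward(self, x, train):
        self._cols = self._im2col(x)
        Wf = self.W.reshape(-1, self.W.shape[2])
        return self._cols @ Wf + self.b

    def backward(self, grad):
        # first layer of the CNN: input gradient never needed
        cols = self._cols.reshape(-1, self._cols.shape[2])
        g = grad.reshape(-1, grad.shape[2])
        self.dW = (cols.T @ g).reshape(self.W.shape)
        self.db = g.sum(axis=0)
        return None

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool1D:
    """Non-overlapping pooling along axis 1 (window == stride)."""

    params: list = []
    grads: list = []

    def __init__(self, window: int):
        if window <= 0:
            raise ValueError("pool window must be positive")
        self.window = window

    def forward(self, x, train):
        n, length, c = x.shape
        usable = (length // self.window) * self.window
        self._trim = (x.shape, usable)
        xr = x[:, :usable].reshape(n, usable // self.window, self.window, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        (shape, usable) = self._trim
        n, _, c = shape
        out = np.zeros(shape, dtype=np.float32)
        outr = out[:, :usable].reshape(n, usable // self.window, self.window, c)
        ni, pi, ci = np.indices(self._argmax.shape)
        outr[ni, pi, self._argmax, ci] = grad
        return out


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Network:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x.ravel()

    def predict_proba(self, x):
        return _sigmoid(self.forward(x, train=False))

    def train_step(self, x, y, optimizer):
        logits = self.forward(x, train=True)
        p = _sigmoid(logits)
        loss = _bce(p, y)
        grad = ((p - y) / len(y)).astype(np.float32)[:, None]
        for l in reversed(self.layers):
            grad = l.backward(grad)
            if grad is None:
                break
        optimizer.step(self.grads)
        return loss

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _bce(p, y, eps=1e-7):
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
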