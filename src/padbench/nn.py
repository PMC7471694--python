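"""Compact numpy trainer for the benchmark's feed-forward and 1D-conv models.

Implements exactly the layer inventory the benchmark needs — dense layers,
length-preserving 1D convolutions (stride 1, "same" zero boundary), a
parallel stack of convolutions concatenated on the filter axis, dropout,
and sigmoid / softmax heads — with Adam and seeded initialisation, so runs
are reproducible on a single CPU.

Inputs are one-hot matrices of shape ``(channels, T)``; batches are
``(B, channels, T)`` float32 arrays.  Convolution keeps the temporal
length, so first-conv activations always have shape ``(filters, T)``.
"""

from __future__ import annotations

import numpy as np


class TrainingDiverged(RuntimeError):
    """Non-finite loss encountered; carries the 1-based epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def forward(self, x, train=False):
        out = np.maximum(x, 0.0)
        self._mask = out > 0 if train else None
        return out

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class Flatten:
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params(self):
        return []


class Conv1D:
    """Stride-1, length-preserving 1D convolution over ``(B, C, T)`` input."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        self.C, self.F, self.K = in_channels, filters, kernel
        fan_in = in_channels * kernel
        self.W = _glorot(rng, (filters, in_channels, kernel), fan_in, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.pl = (kernel - 1) // 2

    def _im2col(self, x):
        B, C, T = x.shape
        pr = self.K - 1 - self.pl
        xp = np.pad(x, ((0, 0), (0, 0), (self.pl, pr)))
        # (B, C, T, K) windows -> (B*T, C*K) patch matrix
        win = np.stack([xp[:, :, k:k + T] for k in range(self.K)], axis=-1)
        return win.transpose(0, 2, 1, 3).reshape(B * T, C * self.K)

    def forward(self, x, train=False):
        B, C, T = x.shape
        cols = self._im2col(x)
        self._cols, self._in_shape = (cols, x.shape) if train else (None, x.shape)
        out = cols @ self.W.reshape(self.F, -1).T + self.b
        return out.reshape(B, T, self.F).transpose(0, 2, 1)

    def backward(self, dy):
        B, C, T = self._in_shape
        dyt = dy.transpose(0, 2, 1).reshape(B * T, self.F)
        self.dW = (dyt.T @ self._cols).reshape(self.F, self.C, self.K)
        self.db = dyt.sum(axis=0)
        dcols = (dyt @ self.W.reshape(self.F, -1)).reshape(B, T, self.C, self.K)
        pr = self.K - 1 - self.pl
        dxp = np.zeros((B, C, T + self.K - 1), dtype=np.float32)
        for k in range(self.K):
            dxp[:, :, k:k + T] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, self.pl:self.pl + T] if self.K > 1 else dxp

    def params(self):
        return [("W", self), ("b", self)]


class ParallelConv:
    """Several Conv1D branches on the same input, concatenated filter-wise."""

    def __init__(self, branches: list[Conv1D]):
        self.branches = branches

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        return sum(b.backward(p) for b, p in zip(self.branches, parts))

    def params(self):
        return [p for b in self.branches for p in b.params()]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A layer pipeline with a sigmoid (binary) or softmax head."""

    def __init__(self, layers: list, head: str):
        if head not in ("sigmoid", "softmax"):
            raise ValueError(f"head must be 'sigmoid' or 'softmax', got {head!r}")
        self.layers = layers
        self.head = head

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        """Raw predicted probabilities: ``(B,)`` binary or ``(B, k)`` softmax."""
        outs = []
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i:i + batch_size], train=False)
            outs.append(_sigmoid(z[:, 0]) if self.head == "sigmoid" else _softmax(z))
        return np.concatenate(outs, axis=0)

    def loss_and_backward(self, x, y) -> float:
        """Mean cross-entropy on one batch; leaves gradients on the layers."""
        z = self.forward(x, train=True)
        B = len(x)
        eps = 1e-12
        if self.head == "sigmoid":
            p = _sigmoid(z[:, 0])
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            dz = ((p - y) / B).astype(np.float32)[:, None]
        else:
            p = _softmax(z)
            loss = -np.mean(np.log(p[np.arange(B), y] + eps))
            dz = p.astype(np.float32)
            dz[np.arange(B), y] -= 1.0
            dz /= B
        dy = dz
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return float(loss)

    def parameters(self):
        return [p for layer in self.layers for p in layer.params()]

    def get_weights(self):
        return [(getattr(obj, name)).copy() for name, obj in self.parameters()]

    def set_weights(self, weights):
        for (name, obj), w in zip(self.parameters(), weights):
            setattr(obj, name, w.copy())

    def first_conv_activations(self, x, batch_size: int = 64) -> np.ndarray:
        """Post-ReLU activations of the first convolution stage, ``(B, F, T)``."""
        conv_idx = next(
            (i for i, l in enumerate(self.layers) if isinstance(l, (Conv1D, ParallelConv))),
            None)
        if conv_idx is None:
            raise ValueError("network has no convolution stage")
        stop = conv_idx + 1
        if stop < len(self.layers) and isinstance(self.layers[stop], ReLU):
            stop += 1
        outs = []
        for i in range(0, len(x), batch_size):
            h = x[i:i + batch_size]
            for layer in self.layers[:stop]:
                h = layer.forward(h, train=False)
            outs.append(h)
        return np.concatenate(outs, axis=0)


class Adam:
    """Adam with the benchmark defaults (lr 1e-4, beta1 0.9, beta2 0.999)."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.v = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (name, obj) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            update = self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            setattr(obj, name, getattr(obj, name) - update.astype(np.float32))
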