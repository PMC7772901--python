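"""Seeded NumPy feed-forward engine behind the model builders.

Implements exactly the pieces the two architectures need — valid (no padding)
1-D convolution, 1-D max pooling, dense layers, ReLU / sigmoid / softmax,
binary and categorical cross-entropy, and Adam — with hand-written forward and
backward passes.  Every parameter draw comes from a single
``numpy.random.Generator``, so a network is fully determined by its
initialisation seed, and training is fully determined by (seed, data order).

Array conventions
-----------------
Convolutional branches carry ``(batch, length, channels)`` arrays; dense
branches and the fused head carry ``(batch, features)``.  Flattening a
``(batch, L, C)`` feature map is time-major: sample ``t``'s ``C`` filter
responses are contiguous.  Branch outputs are concatenated in the fixed order
the model graph declares.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "relu",
    "sigmoid",
    "softmax",
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "Flatten",
    "Network",
    "Adam",
    "loss_and_grad",
]


# ---------------------------------------------------------------------------
# activations


def relu(v: np.ndarray) -> np.ndarray:
    """Rectified linear unit, ``max(0, v)`` elementwise."""
    return np.maximum(np.asarray(v, dtype=float), 0.0)


def sigmoid(v: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function ``1 / (1 + e^-v)``."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Max-shifted softmax along ``axis``; rows sum to one."""
    v = np.asarray(v, dtype=float)
    z = v - np.max(v, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# layers


class Dense:
    """Fully connected layer with optional fused ReLU.

    Weights use Glorot (variance-scaling) uniform initialisation,
    ``U(-sqrt(6/(n_in+n_out)), +sqrt(6/(n_in+n_out)))``; biases start at zero.
    """

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported dense activation: {activation!r}")
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.activation = activation

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.activation == "relu":
            g = g * self._mask
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Conv1D:
    """1-D convolution, valid padding, arbitrary stride, fused ReLU.

    Input ``(batch, L, c_in)`` → output ``(batch, floor((L-k)/s)+1, n_filters)``.
    Implemented as im2col + matmul; the backward pass scatter-adds the column
    gradients back onto the input grid.
    """

    def __init__(self, c_in: int, n_filters: int, kernel: int, stride: int,
                 activation: str, rng: np.random.Generator):
        if activation != "relu":
            raise ValueError(f"unsupported conv activation: {activation!r}")
        fan_in = kernel * c_in
        fan_out = kernel * n_filters
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        # W rows ordered (c_in, kernel-tap) to match the im2col layout below
        self.W = rng.uniform(-limit, limit, size=(c_in * kernel, n_filters))
        self.b = np.zeros(n_filters)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.c_in = c_in
        self.n_filters = n_filters
        self.kernel = kernel
        self.stride = stride

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        if L < self.kernel:
            raise ValueError(
                f"conv input length {L} shorter than kernel {self.kernel}")
        # (n, out_len, c, kernel)
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        cols = cols[:, ::self.stride]
        self._cols = cols
        self._in_shape = x.shape
        out_len = cols.shape[1]
        z = cols.reshape(n, out_len, c * self.kernel) @ self.W + self.b
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g * self._mask
        n, out_len, _ = g.shape
        cols2d = self._cols.reshape(n * out_len, self.c_in * self.kernel)
        g2d = g.reshape(n * out_len, self.n_filters)
        self.gW[...] = cols2d.T @ g2d
        self.gb[...] = g2d.sum(axis=0)
        gcols = (g2d @ self.W.T).reshape(n, out_len, self.c_in, self.kernel)
        gx = np.zeros(self._in_shape)
        for j in range(self.kernel):
            gx[:, j:j + out_len * self.stride:self.stride, :] += gcols[:, :, :, j]
        return gx


class MaxPool1D:
    """1-D max pooling, valid windows, arbitrary stride. No parameters."""

    params: list = []
    grads: list = []

    def __init__(self, pool: int, stride: int):
        self.pool = pool
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        # (n, out_len, c, pool)
        win = np.lib.stride_tricks.sliding_window_view(x, self.pool, axis=1)
        win = win[:, ::self.stride]
        self._argmax = win.argmax(axis=3)
        self._in_shape = x.shape
        return win.max(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n_i, o_i, c_i = np.indices(self._argmax.shape, sparse=True)
        gx = np.zeros(self._in_shape)
        np.add.at(gx, (n_i, o_i * self.stride + self._argmax, c_i), g)
        return gx


class Flatten:
    """(batch, L, C) → (batch, L·C), time-major."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._in_shape)


# ---------------------------------------------------------------------------
# network


class Network:
    """Multi-branch feed-forward network with a fused dense head.

    ``branches`` is an ordered list of ``(name, [layers])``; inputs are looked
    up by branch name, so the caller's dict ordering is irrelevant — the
    concatenation order is the declared branch order.  The final head layer is
    linear; ``out_activation`` ('sigmoid' or 'softmax') is applied only at
    prediction time, the losses work on logits.
    """

    def __init__(self, branches, head, out_activation: str, task: str):
        self.branches = branches
        self.head = head
        self.out_activation = out_activation
        self.task = task

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def parameters(self):
        out = []
        for _, layers in self.branches:
            for ly in layers:
                out.extend(ly.params)
        for ly in self.head:
            out.extend(ly.params)
        return out

    def gradients(self):
        out = []
        for _, layers in self.branches:
            for ly in layers:
                out.extend(ly.grads)
        for ly in self.head:
            out.extend(ly.grads)
        return out

    def forward(self, inputs: dict) -> np.ndarray:
        outs = []
        for name, layers in self.branches:
            try:
                x = np.asarray(inputs[name], dtype=float)
            except KeyError:
                raise KeyError(f"missing input for branch {name!r}") from None
            for ly in layers:
                x = ly.forward(x)
            if x.ndim != 2:
                x = x.reshape(x.shape[0], -1)
            outs.append(x)
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        h = np.concatenate(outs, axis=1)
        for ly in self.head:
            h = ly.forward(h)
        return h

    def backward(self, g_logits: np.ndarray) -> None:
        g = g_logits
        for ly in reversed(self.head):
            g = ly.backward(g)
        parts = np.split(g, self._split, axis=1)
        for (name, layers), gp in zip(self.branches, parts):
            for ly in reversed(layers):
                gp = ly.backward(gp)

    def predict_proba(self, inputs: dict) -> np.ndarray:
        z = self.forward(inputs)
        if self.out_activation == "sigmoid":
            return sigmoid(z)
        return softmax(z, axis=1)

    def predict(self, inputs: dict) -> np.ndarray:
        p = self.predict_proba(inputs)
        if self.out_activation == "sigmoid":
            return (p[:, 0] > 0.5).astype(int)
        return p.argmax(axis=1)


# ---------------------------------------------------------------------------
# losses and optimiser


def loss_and_grad(logits: np.ndarray, y: np.ndarray, kind: str):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``binary_cross_entropy`` expects logits ``(n, 1)`` and labels in {0,1};
    ``categorical_cross_entropy`` expects logits ``(n, K)`` and integer labels.
    Both are computed in log-sum-exp form, so no probability ever underflows.
    """
    n = logits.shape[0]
    if kind == "binary_cross_entropy":
        z = logits[:, 0]
        y = np.asarray(y, dtype=float)
        loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        g = ((sigmoid(z) - y) / n)[:, None]
        return loss, g
    if kind == "categorical_cross_entropy":
        y = np.asarray(y, dtype=int)
        zmax = logits.max(axis=1, keepdims=True)
        lse = zmax[:, 0] + np.log(np.exp(logits - zmax).sum(axis=1))
        loss = float(np.mean(lse - logits[np.arange(n), y]))
        g = softmax(logits, axis=1)
        g[np.arange(n), y] -= 1.0
        return loss, g / n
    raise ValueError(f"unknown loss kind: {kind!r}")


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
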