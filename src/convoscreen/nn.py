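"""Minimal reverse-mode autodiff and the neural classifiers built on it.

A small tensor graph (numpy arrays, topological-order backprop) supports
exactly the operations the three classifier architectures need: broadcast
arithmetic, batched matmul, pointwise nonlinearities, axis reductions,
reshape/transpose/slice/concat, layer normalization, dropout and a
numerically stable softmax cross-entropy. Gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Adam",
    "MLPClassifier",
    "LSTMClassifier",
    "TransformerClassifier",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = np.moveaxis(a, -1, 0).reshape(a.shape[-1], -1) @ g.ravel()
            elif a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.outer(a, g)
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: (g * (1.0 - out.data**2),)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: (g * out.data * (1.0 - out.data),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: (g.transpose(*inv),)
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    @staticmethod
    def cat(tensors, axis=0):
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        shift = self - self.data.max(axis=axis, keepdims=True)  # constant shift
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward pass ---------------------------------------------------
    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad and g is not None:
                    p.grad = p.grad + g if p.grad is not None else g


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gamma + beta


def dropout(x: Tensor, p: float, rng, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets from raw logits."""
    n, k = logits.shape
    shift = logits - logits.data.max(axis=1, keepdims=True)
    lse = shift.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    picked = (shift * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _glorot(rng, *shape) -> Tensor:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class _BaseNet:
    """Shared 10-epoch Adam training loop (cross-entropy, batch size 8)."""

    epochs = 10
    batch_size = 8
    lr = 1e-3

    def fit(self, X, y, log: list | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        opt = Adam(self.parameters(), lr=self.lr)
        n = len(X)
        self.training_log = []
        for epoch in range(self.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                opt.zero_grad()
                logits = self.forward(X[idx], training=True)
                loss = cross_entropy(logits, y[idx])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.training_log.append(float(np.mean(losses)))
        if log is not None:
            log.extend(self.training_log)
        return self

    def predict_proba(self, X):
        logits = self.forward(np.asarray(X, dtype=np.float64), training=False)
        return logits.softmax(axis=-1).data

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


class MLPClassifier(_BaseNet):
    """One hidden layer of 64 ReLU units with dropout 0.3, for static
    feature vectors (demographics, document embeddings)."""

    def __init__(self, n_features: int, hidden: int = 64, dropout_p: float = 0.3,
                 seed: int = 0, n_classes: int = 2):
        self._rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.dropout_p = dropout_p
        self.W1 = _glorot(self._rng, n_features, hidden)
        self.b1 = _zeros(hidden)
        self.W2 = _glorot(self._rng, hidden, n_classes)
        self.b2 = _zeros(n_classes)

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, X, training: bool) -> Tensor:
        h = (Tensor(X) @ self.W1 + self.b1).relu()
        h = dropout(h, self.dropout_p, self._rng, training)
        return h @ self.W2 + self.b2


class LSTMClassifier(_BaseNet):
    """Single-layer LSTM (hidden size 128); the final hidden state feeds a
    linear head. Inputs are (batch, frames, dim) uniformly resampled
    sequences."""

    def __init__(self, n_features: int, hidden: int = 128, seed: int = 0,
                 n_classes: int = 2):
        self._rng = np.random.default_rng(seed)
        self.hidden = hidden
        h = hidden
        self.Wx = _glorot(self._rng, n_features, 4 * h)
        self.Wh = _glorot(self._rng, h, 4 * h)
        self.b = _zeros(4 * h)
        self.Wo = _glorot(self._rng, h, n_classes)
        self.bo = _zeros(n_classes)

    def parameters(self):
        return [self.Wx, self.Wh, self.b, self.Wo, self.bo]

    def forward(self, X, training: bool) -> Tensor:
        B, T, _ = X.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        xt = Tensor(X)
        for t in range(T):
            gates = xt[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h @ self.Wo + self.bo


class TransformerClassifier(_BaseNet):
    """Encoder-only transformer with a classification token.

    Embedding dim 128, 4 attention heads, 2 pre-norm encoder layers with
    32-unit MLPs, dropout 0.1; a learned [CLS] token prepended to the
    projected sequence carries the decision. Inputs are (batch, frames,
    dim) uniformly resampled sequences.
    """

    def __init__(self, n_features: int, seq_len: int, embed: int = 128,
                 mlp_hidden: int = 32, n_heads: int = 4, n_layers: int = 2,
                 dropout_p: float = 0.1, seed: int = 0, n_classes: int = 2):
        if embed % n_heads:
            raise ValueError("embedding dim must divide across heads")
        self._rng = np.random.default_rng(seed)
        self.embed, self.n_heads, self.n_layers = embed, n_heads, n_layers
        self.dropout_p = dropout_p
        rng = self._rng
        self.proj = _glorot(rng, n_features, embed)
        self.cls = Tensor(rng.normal(0, 0.02, size=(1, 1, embed)), requires_grad=True)
        self.pos = Tensor(rng.normal(0, 0.02, size=(1, seq_len + 1, embed)),
                          requires_grad=True)
        self.layers = []
        for _ in range(n_layers):
            self.layers.append(
                {
                    "ln1_g": Tensor(np.ones(embed), requires_grad=True),
                    "ln1_b": _zeros(embed),
                    "Wq": _glorot(rng, embed, embed),
                    "Wk": _glorot(rng, embed, embed),
                    "Wv": _glorot(rng, embed, embed),
                    "Wo": _glorot(rng, embed, embed),
                    "ln2_g": Tensor(np.ones(embed), requires_grad=True),
                    "ln2_b": _zeros(embed),
                    "W1": _glorot(rng, embed, mlp_hidden),
                    "b1": _zeros(mlp_hidden),
                    "W2": _glorot(rng, mlp_hidden, embed),
                    "b2": _zeros(embed),
                }
            )
        self.ln_f_g = Tensor(np.ones(embed), requires_grad=True)
        self.ln_f_b = _zeros(embed)
        self.head_W = _glorot(rng, embed, n_classes)
        self.head_b = _zeros(n_classes)

    def parameters(self):
        params = [self.proj, self.cls, self.pos, self.ln_f_g, self.ln_f_b,
                  self.head_W, self.head_b]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    def _attention(self, x: Tensor, layer, training: bool) -> Tensor:
        B, T, E = x.shape
        H, Dh = self.n_heads, E // self.n_heads

        def heads(t):
            return t.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)

        q, k, v = heads(x @ layer["Wq"]), heads(x @ layer["Wk"]), heads(x @ layer["Wv"])
        scores = (q @ k.swapaxes(-1, -2)) * (Dh**-0.5)
        attn = scores.softmax(axis=-1)
        attn = dropout(attn, self.dropout_p, self._rng, training)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
        return out @ layer["Wo"]

    def forward(self, X, training: bool) -> Tensor:
        B, T, _ = X.shape
        x = Tensor(X) @ self.proj
        cls = Tensor(np.ones((B, 1, 1))) * self.cls
        x = Tensor.cat([cls, x], axis=1) + self.pos[:, : T + 1, :]
        x = dropout(x, self.dropout_p, self._rng, training)
        for layer in self.layers:
            a = self._attention(
                layer_norm(x, layer["ln1_g"], layer["ln1_b"]), layer, training
            )
            x = x + dropout(a, self.dropout_p, self._rng, training)
            h = (layer_norm(x, layer["ln2_g"], layer["ln2_b"]) @ layer["W1"]
                 + layer["b1"]).relu()
            h = h @ layer["W2"] + layer["b2"]
            x = x + dropout(h, self.dropout_p, self._rng, training)
        x = layer_norm(x, self.ln_f_g, self.ln_f_b)
        return x[:, 0, :] @ self.head_W + self.head_b
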