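"""A small numpy neural-network engine for the codon-aware classifier.

The classifier needs three things from its compute engine: a forward pass
over zero-padded one-hot alignment batches, parameter gradients for Adam
training, and *input* gradients for saliency maps.  All three are provided
by hand-written forward/backward passes in float64, which keeps training
bit-reproducible for a fixed seed and makes finite-difference verification
of the gradients straightforward.

Layer conventions
-----------------
* The input tensor has shape (B, n, L, 5): batch, taxa rows, alignment
  columns, character channels.
* The first convolution uses an n x 3 filter with stride 3 along columns, so
  each output position sees exactly one codon column of the whole alignment;
  after it the representation is (B, m, C) with m = L/3 codon columns.
* Later convolutions are width-3, stride-1, same-padded over codon columns.
* Average pooling halves the column count (floor semantics, remainder
  dropped); when a feature map is already shorter than the pool width the
  pool is the identity, so deep stacks remain well-defined on short genes.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CodonConv(Layer):
    """n x 3 filter, stride 3: one output position per codon column."""

    def __init__(self, n_taxa: int, filters: int, rng):
        self.n_taxa = n_taxa
        fan_in = n_taxa * 3 * 5
        self.W = Parameter(
            glorot_uniform((fan_in, filters), fan_in, filters, rng), "codon_conv.W"
        )
        self.b = Parameter(np.zeros(filters), "codon_conv.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        B, n, L, C = x.shape
        if n != self.n_taxa:
            raise ValueError(
                f"input has {n} taxon rows but the model expects {self.n_taxa}"
            )
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} is not divisible by 3")
        m = L // 3
        # (B, n, m, 3, C) -> (B, m, n*3*C)
        xr = x.reshape(B, n, m, 3, C).transpose(0, 2, 1, 3, 4).reshape(B, m, -1)
        self._cache = (xr, (B, n, L, C))
        return xr @ self.W.value + self.b.value

    def backward(self, grad):
        xr, (B, n, L, C) = self._cache
        self.W.grad += np.einsum("bmi,bmf->if", xr, grad)
        self.b.grad += grad.sum(axis=(0, 1))
        dxr = grad @ self.W.value.T
        m = L // 3
        return (
            dxr.reshape(B, m, n, 3, C).transpose(0, 2, 1, 3, 4).reshape(B, n, L, C)
        )


class Conv1D(Layer):
    """Width-k, stride-1, same-padded convolution over codon columns."""

    def __init__(self, in_channels: int, filters: int, rng, kernel_width: int = 3):
        self.k = kernel_width
        self.cin = in_channels
        fan_in = kernel_width * in_channels
        self.W = Parameter(
            glorot_uniform((fan_in, filters), fan_in, filters, rng), "conv1d.W"
        )
        self.b = Parameter(np.zeros(filters), "conv1d.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        B, m, C = x.shape
        p = (self.k - 1) // 2
        xp = np.zeros((B, m + self.k - 1, C))
        xp[:, p : p + m] = x
        cols = np.stack([xp[:, i : i + m] for i in range(self.k)], axis=2)
        cols = cols.reshape(B, m, self.k * C)
        self._cache = (cols, (B, m, C), p)
        return cols @ self.W.value + self.b.value

    def backward(self, grad):
        cols, (B, m, C), p = self._cache
        self.W.grad += np.einsum("bmi,bmf->if", cols, grad)
        self.b.grad += grad.sum(axis=(0, 1))
        dcols = (grad @ self.W.value.T).reshape(B, m, self.k, C)
        dxp = np.zeros((B, m + self.k - 1, C))
        for i in range(self.k):
            dxp[:, i : i + m] += dcols[:, :, i]
        return dxp[:, p : p + m]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(Layer):
    """Per-channel normalization over batch and column axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, train, x.size // x.shape[-1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, train, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        if not train:
            return grad * self.gamma.value * inv
        g = grad * self.gamma.value
        return (
            inv / n * (n * g - g.sum(axis=axes) - xhat * (g * xhat).sum(axis=axes))
        )


class Dropout(Layer):
    def __init__(self, p: float, rng):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPool(Layer):
    """Width-w column pooling with floor semantics; identity on short maps."""

    def __init__(self, width: int = 2):
        self.w = width

    def forward(self, x, train):
        B, m, C = x.shape
        if m < self.w:
            self._cache = None
            return x
        m2 = m // self.w
        self._cache = (m, m2)
        return x[:, : m2 * self.w].reshape(B, m2, self.w, C).mean(axis=2)

    def backward(self, grad):
        if self._cache is None:
            return grad
        m, m2 = self._cache
        B, _, C = grad.shape
        dx = np.zeros((B, m, C))
        dx[:, : m2 * self.w] = np.repeat(grad / self.w, self.w, axis=1)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._m = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._m, axis=1) / self._m


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        self.W = Parameter(
            glorot_uniform((in_features, out_features), in_features, out_features, rng),
            "dense.W",
        )
        self.b = Parameter(np.zeros(out_features), "dense.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Network:
    """A sequential stack ending in a single-logit dense layer.

    ``forward`` returns sigmoid scores in [0, 1]; the binary cross-entropy
    gradient is taken with respect to the logit for numerical stability.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, (CodonConv, Conv1D)) for l in self.layers)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return sigmoid(self.forward_logits(x, train))

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        grad = dlogit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: "Adam") -> float:
        """One Adam update on a batch; returns the mean BCE loss."""
        self.zero_grad()
        logits = self.forward_logits(x, train=True)
        probs = sigmoid(logits)
        eps = 1e-12
        loss = float(
            -np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        )
        self.backward((probs - y) / len(y))
        optimizer.step(self.params())
        return loss

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d score / d input at x (inference mode), shape = x.shape."""
        self.zero_grad()
        logits = self.forward_logits(x, train=False)
        z = sigmoid(logits)
        return self.backward(z * (1 - z))

    # -- weight (de)serialization -----------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"layer{i}.param{j}"] = p.value
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value[...] = state[f"layer{i}.param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[Parameter]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in params:
            key = id(p)
            m = self._m.setdefault(key, np.zeros_like(p.value))
            v = self._v.setdefault(key, np.zeros_like(p.value))
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
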