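"""Minimal reverse-mode neural-network primitives (numpy).

Dense / batch-norm / leaky-ReLU / dropout layers with hand-derived
backward passes, a Sequential container, and an Adam optimizer.  Only what
the linearizing PRS models need; training is mini-batch on CPU.

Layer parameter state is exposed as an ordered ``{name: array}`` dict so
model checkpoints can be serialized to a single ``.npz`` container.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Persistent state: parameters plus non-trained buffers."""
        return self.params()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.state().items():
            v[...] = state[k]


class Dense(Layer):
    """Affine map x @ W + b with Kaiming-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm(Layer):
    """1-d batch normalization with running statistics for eval mode."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self._cache = None

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv
            self._cache = (xhat, inv)
            return self.gamma * xhat + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) * inv + self.beta

    def backward(self, dout):
        xhat, inv = self._cache
        nb = dout.shape[0]
        self.dgamma[...] = (dout * xhat).sum(axis=0)
        self.dbeta[...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (inv / nb) * (nb * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))

    def eval_scale(self) -> np.ndarray:
        """Per-unit linear slope of the eval-mode map (gamma / sqrt(var+eps))."""
        return self.gamma / np.sqrt(self.running_var + self.eps)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x, train):
        mask = np.where(x >= 0, 1.0, self.slope)
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dout):
        return dout * self._mask

    def slopes_at(self, x: np.ndarray) -> np.ndarray:
        return np.where(x >= 0, 1.0, self.slope)


class Dropout(Layer):
    """Inverted dropout: scales by 1/(1-p) at train time, identity in eval."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self.rate == 0.0 or self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return {f"l{i}.{k}": v for i, layer in enumerate(self.layers)
                for k, v in layer.params().items()}

    def grads(self):
        return {f"l{i}.{k}": v for i, layer in enumerate(self.layers)
                for k, v in layer.grads().items()}

    def state(self):
        return {f"l{i}.{k}": v for i, layer in enumerate(self.layers)
                for k, v in layer.state().items()}

    def load_state(self, state):
        for i, layer in enumerate(self.layers):
            layer.load_state({k.split(".", 1)[1]: v for k, v in state.items()
                              if k.startswith(f"l{i}.")})


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_from_logits(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Element-wise binary cross-entropy from pre-sigmoid scores,
    softplus(z) - y*z, numerically stable."""
    return np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
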