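"""The multi-task linearizing network (MTL LINA) and the single-task baseline.

The MTL model predicts d binary traits from an m-SNP genotype vector X as

    Y = sigmoid(K (A o X) + B),      A = F(X),

where F is a feedforward attention subnetwork (three hidden layers, default
1000/250/50 units, each affine -> batch-norm -> leaky-ReLU -> dropout, then a
linear m-unit attention layer), ``o`` is the element-wise product, K a d x m
coefficient matrix and B a d-vector of biases.  Because the readout is affine
in (A o X), the model is *exactly* a per-trait linear model once A is known —
the property the interpretation module exploits.

The training loss is  W'E + beta * ||K||_2  with E the vector of per-trait
mean binary cross-entropies, W per-trait loss weights (default all ones) and
||.||_2 the Frobenius norm (a squared-norm variant is available via config).

The STL baseline is a plain feedforward net of the same hidden geometry with
a single sigmoid output, trained with cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm, Dense, Dropout, LeakyReLU, Sequential, sigmoid

CHECKPOINT_SCHEMA = 1


@dataclass
class MTLModelConfig:
    n_snps: int
    n_traits: int
    hidden_sizes: tuple[int, int, int] = (1000, 250, 50)
    dropout_rate: float = 0.5
    leaky_slope: float = 0.01
    beta: float = 1e-3
    loss_weights: np.ndarray | None = None
    squared_penalty: bool = False

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3:
            raise ValueError("hidden_sizes must have length 3")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.loss_weights is None:
            self.loss_weights = np.ones(self.n_traits)
        self.loss_weights = np.asarray(self.loss_weights, dtype=float)
        if self.loss_weights.shape != (self.n_traits,) or (self.loss_weights < 0).any():
            raise ValueError("loss_weights must be d nonnegative values")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["loss_weights"] = [float(w) for w in self.loss_weights]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MTLModelConfig":
        d = dict(d)
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


@dataclass
class LossBreakdown:
    """total = loss_weights . per_trait_ce + penalty, exactly by construction."""

    per_trait_ce: np.ndarray
    penalty: float
    total: float


def _hidden_block(n_in: int, n_out: int, cfg, rng, drop_rng) -> list[_nn.Layer]:
    return [
        Dense(n_in, n_out, rng),
        BatchNorm(n_out),
        LeakyReLU(cfg.leaky_slope),
        Dropout(cfg.dropout_rate, drop_rng),
    ]


class MTLModel:
    """Trainable MTL LINA model; see module docstring for the equations."""

    kind = "mtl"

    def __init__(self, config: MTLModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        h1, h2, h3 = config.hidden_sizes
        m, d = config.n_snps, config.n_traits
        layers: list[_nn.Layer] = []
        for a, b in ((m, h1), (h1, h2), (h2, h3)):
            layers += _hidden_block(a, b, config, rng, self._drop_rng)
        layers.append(Dense(h3, m, rng))  # linear attention layer
        self.net = Sequential(layers)
        self.K = rng.normal(0.0, 1.0 / np.sqrt(m), size=(d, m))
        self.B = np.zeros(d)
        self.dK = np.zeros_like(self.K)
        self.dB = np.zeros_like(self.B)

    # -- forward ---------------------------------------------------------
    def attention(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = self._check_input(X)
        return self.net.forward(X, train)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return sigmoid(self.scores(X, train))

    def scores(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-sigmoid outputs Z = K (A o X) + B."""
        X = self._check_input(X)
        A = self.net.forward(X, train)
        return (A * X) @ self.K.T + self.B

    predict_proba = forward

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_snps:
            raise ValueError(f"input must be (batch, {self.config.n_snps})")
        return X

    def set_output_bias(self, prevalences: np.ndarray) -> None:
        """Initialize B at logit(prevalence) so the untrained model predicts
        the base rates (standard for rare binary outcomes)."""
        p = np.clip(np.asarray(prevalences, dtype=float), 1e-6, 1 - 1e-6)
        self.B[...] = np.log(p / (1 - p))

    # -- loss ------------------------------------------------------------
    def loss(self, X: np.ndarray, Y_true: np.ndarray, train: bool = False) -> LossBreakdown:
        Y_true = self._check_targets(X, Y_true)
        Z = self.scores(X, train)
        return self._breakdown(Z, Y_true)

    def _check_targets(self, X, Y_true) -> np.ndarray:
        Y_true = np.asarray(Y_true)
        if not np.isin(Y_true, (0, 1)).all():
            raise ValueError("targets must be binary 0/1")
        if Y_true.shape != (np.shape(X)[0], self.config.n_traits):
            raise ValueError("target shape mismatch")
        return Y_true.astype(float)

    def _breakdown(self, Z: np.ndarray, Y_true: np.ndarray) -> LossBreakdown:
        E = _nn.bce_from_logits(Z, Y_true).mean(axis=0)
        fro = np.linalg.norm(self.K)
        penalty = self.config.beta * (fro**2 if self.config.squared_penalty else fro)
        total = float(self.config.loss_weights @ E + penalty)
        return LossBreakdown(per_trait_ce=E, penalty=float(penalty), total=total)

    def loss_and_grads(self, X: np.ndarray, Y_true: np.ndarray) -> LossBreakdown:
        """Train-mode forward + full backward; gradients land in grads()."""
        X = self._check_input(X)
        Y_true = self._check_targets(X, Y_true)
        A = self.net.forward(X, train=True)
        U = A * X
        Z = U @ self.K.T + self.B
        out = self._breakdown(Z, Y_true)
        nb = X.shape[0]
        dZ = (sigmoid(Z) - Y_true) * self.config.loss_weights / nb
        fro = np.linalg.norm(self.K)
        if self.config.squared_penalty:
            dpen = 2.0 * self.config.beta * self.K
        else:
            dpen = self.config.beta * self.K / max(fro, 1e-12)
        self.dK[...] = dZ.T @ U + dpen
        self.dB[...] = dZ.sum(axis=0)
        dA = (dZ @ self.K) * X
        self.net.backward(dA)
        return out

    # -- parameter plumbing ---------------------------------------------
    def params(self) -> dict[str, np.ndarray]:
        p = {f"net.{k}": v for k, v in self.net.params().items()}
        p["K"] = self.K
        p["B"] = self.B
        return p

    def grads(self) -> dict[str, np.ndarray]:
        g = {f"net.{k}": v for k, v in self.net.grads().items()}
        g["K"] = self.dK
        g["B"] = self.dB
        return g

    def state(self) -> dict[str, np.ndarray]:
        s = {f"net.{k}": v for k, v in self.net.state().items()}
        s["K"] = self.K
        s["B"] = self.B
        return s

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state({k[4:]: v for k, v in state.items() if k.startswith("net.")})
        self.K[...] = state["K"]
        self.B[...] = state["B"]

    def save(self, path: str | Path) -> None:
        save_checkpoint(self, path)


class STLModel:
    """Single-task feedforward baseline with one sigmoid output."""

    kind = "stl"

    def __init__(self, config: MTLModelConfig, seed: int = 0):
        if config.n_traits != 1:
            raise ValueError("STL models have a single output trait")
        self.config = config
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        h1, h2, h3 = config.hidden_sizes
        layers: list[_nn.Layer] = []
        for a, b in ((config.n_snps, h1), (h1, h2), (h2, h3)):
            layers += _hidden_block(a, b, config, rng, self._drop_rng)
        layers.append(Dense(h3, 1, rng))
        self.net = Sequential(layers)

    def scores(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_snps:
            raise ValueError(f"input must be (batch, {self.config.n_snps})")
        return self.net.forward(X, train)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return sigmoid(self.scores(X, train))

    predict_proba = forward

    def set_output_bias(self, prevalences: np.ndarray) -> None:
        p = float(np.clip(np.asarray(prevalences, dtype=float).ravel()[0], 1e-6, 1 - 1e-6))
        self.net.layers[-1].b[...] = np.log(p / (1 - p))

    def loss(self, X: np.ndarray, Y_true: np.ndarray, train: bool = False) -> LossBreakdown:
        Z = self.scores(X, train)
        E = _nn.bce_from_logits(Z, self._targets(X, Y_true)).mean(axis=0)
        return LossBreakdown(per_trait_ce=E, penalty=0.0, total=float(E.sum()))

    def _targets(self, X, Y_true) -> np.ndarray:
        Y_true = np.asarray(Y_true, dtype=float).reshape(np.shape(X)[0], 1)
        if not np.isin(Y_true, (0, 1)).all():
            raise ValueError("targets must be binary 0/1")
        return Y_true

    def loss_and_grads(self, X: np.ndarray, Y_true: np.ndarray) -> LossBreakdown:
        Y_true = self._targets(X, Y_true)
        Z = self.scores(X, train=True)
        E = _nn.bce_from_logits(Z, Y_true).mean(axis=0)
        dZ = (sigmoid(Z) - Y_true) / X.shape[0]
        self.net.backward(dZ)
        return LossBreakdown(per_trait_ce=E, penalty=0.0, total=float(E.sum()))

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def state(self):
        return self.net.state()

    def state_copy(self):
        return {k: v.copy() for k, v in self.state().items()}

    def load_state(self, state):
        self.net.load_state(state)

    def save(self, path: str | Path) -> None:
        save_checkpoint(self, path)


def init_model(config: MTLModelConfig, seed: int = 0, kind: str = "mtl"):
    """Reproducibly initialize an MTL or STL model."""
    cls = MTLModel if kind == "mtl" else STLModel
    return cls(config, seed=seed)


def make_optimizer(model, lr: float = 1e-4) -> Adam:
    return Adam(model.params(), lr=lr)


def mtl_loss(model: MTLModel, X: np.ndarray, Y_true: np.ndarray) -> LossBreakdown:
    """Eval-mode loss breakdown: per-trait cross-entropies, the beta*||K||
    penalty and their weighted total."""
    return model.loss(X, Y_true, train=False)


# ---------------------------------------------------------------------------
# Checkpoints: single-file .npz with a JSON config header (schema v1)
# ---------------------------------------------------------------------------

def save_checkpoint(model, path: str | Path) -> None:
    meta = json.dumps({
        "schema": CHECKPOINT_SCHEMA,
        "kind": model.kind,
        "config": model.config.to_dict(),
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.array(meta), **model.state())


def load_checkpoint(path: str | Path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        config = MTLModelConfig.from_dict(meta["config"])
        model = init_model(config, seed=0, kind=meta["kind"])
        model.load_state({k: z[k] for k in z.files if k != "__meta__"})
    return model
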