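"""Per-client neural network: a small MLP over the 8-dim Pa ⊕ Pd features.

The network is written directly in NumPy so that its trainable state is one
flat parameter vector — the object exchanged and averaged by the federation.
Training is plain seeded mini-batch gradient descent on softmax
cross-entropy with an optional L2 penalty: fully deterministic given the
configuration seed and shard order, with no momentum or adaptive state to
reconcile across clients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

N_CLASSES = 3


@dataclass(frozen=True)
class Architecture:
    input_dim: int = 8
    hidden_layers: tuple[int, ...] = (16,)
    n_classes: int = N_CLASSES
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.n_classes != N_CLASSES:
            raise ValueError("n_classes must be 3")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is supported")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_layers, self.n_classes]
        return [(dims[i], dims[i + 1]) for i in range(len(dims) - 1)]

    @property
    def n_params(self) -> int:
        return sum(fi * fo + fo for fi, fo in self.layer_dims)


@dataclass(frozen=True)
class ModelParameters:
    flat: np.ndarray
    arch: Architecture

    def __post_init__(self) -> None:
        flat = np.asarray(self.flat, dtype=float)
        if flat.shape != (self.arch.n_params,):
            raise ValueError(
                f"expected {self.arch.n_params} parameters, got {flat.shape}"
            )
        if not np.all(np.isfinite(flat)):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "flat", flat)

    def unflatten(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Return per-layer (W of shape fan_in×fan_out, b of shape fan_out)."""
        layers = []
        off = 0
        for fi, fo in self.arch.layer_dims:
            w = self.flat[off : off + fi * fo].reshape(fi, fo)
            off += fi * fo
            b = self.flat[off : off + fo]
            off += fo
            layers.append((w, b))
        return layers


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 50
    learning_rate: float = 0.1
    batch_size: int = 16
    seed: int = 0
    l2: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")


def init_params(arch: Architecture, seed: int) -> ModelParameters:
    """Fan-in-scaled uniform weight init, zero biases; deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA5)))
    parts = []
    for fi, fo in arch.layer_dims:
        bound = 1.0 / np.sqrt(fi)
        parts.append(rng.uniform(-bound, bound, size=fi * fo))
        parts.append(np.zeros(fo))
    return ModelParameters(flat=np.concatenate(parts), arch=arch)


def _forward(layers, x: np.ndarray):
    """Return (activations per layer, logits). x is n×input_dim."""
    acts = [x]
    h = x
    for i, (w, b) in enumerate(layers):
        z = h @ w + b
        h = np.maximum(z, 0.0) if i < len(layers) - 1 else z
        acts.append(h)
    return acts, h


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def loss_value(params: ModelParameters, x: np.ndarray, y: np.ndarray, l2: float = 0.0) -> float:
    """Mean softmax cross-entropy plus L2 penalty on the weights."""
    layers = params.unflatten()
    _, logits = _forward(layers, x)
    p = _softmax(logits)
    ce = -np.mean(np.log(np.clip(p[np.arange(len(y)), y], 1e-300, None)))
    reg = 0.5 * l2 * sum(float(np.sum(w * w)) for w, _ in layers)
    return float(ce + reg)


def _gradient(layers, x: np.ndarray, y: np.ndarray, l2: float) -> list:
    acts, logits = _forward(layers, x)
    n = len(y)
    delta = _softmax(logits)
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads = [None] * len(layers)
    for i in range(len(layers) - 1, -1, -1):
        w, _ = layers[i]
        gw = acts[i].T @ delta + l2 * w
        gb = delta.sum(axis=0)
        grads[i] = (gw, gb)
        if i > 0:
            delta = (delta @ w.T) * (acts[i] > 0)
    return grads


def train_local(
    params: ModelParameters, x: np.ndarray, y: np.ndarray, cfg: TrainingConfig
) -> ModelParameters:
    """Mini-batch gradient descent for cfg.epochs; deterministic per cfg.seed.

    Shards smaller than one batch train full-batch. A zero learning rate
    returns the input parameters unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(x) == 0:
        raise ValueError("shard must be non-empty")
    layers = [(w.copy(), b.copy()) for w, b in params.unflatten()]
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xA6)))
    n = len(x)
    bs = min(cfg.batch_size, n)
    # overflow in a diverging run is detected below, not warned about
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                grads = _gradient(layers, x[idx], y[idx], cfg.l2)
                layers = [
                    (w - cfg.learning_rate * gw, b - cfg.learning_rate * gb)
                    for (w, b), (gw, gb) in zip(layers, grads)
                ]
            if not all(
                np.all(np.isfinite(w)) and np.all(np.isfinite(b)) for w, b in layers
            ):
                raise FloatingPointError(
                    "non-finite parameters during training; learning rate too high"
                )
    flat = np.concatenate([np.concatenate([w.ravel(), b]) for w, b in layers])
    return ModelParameters(flat=flat, arch=params.arch)


def predict_proba(params: ModelParameters, features: np.ndarray) -> np.ndarray:
    """Class probabilities (rows sum to 1) for one vector or an n×d matrix."""
    f = np.atleast_2d(np.asarray(features, dtype=float))
    if f.shape[1] != params.arch.input_dim:
        raise ValueError(
            f"feature dim {f.shape[1]} != architecture input {params.arch.input_dim}"
        )
    _, logits = _forward(params.unflatten(), f)
    p = _softmax(logits)
    return p[0] if np.ndim(features) == 1 else p


def predict(params: ModelParameters, features: np.ndarray) -> np.ndarray:
    """Predicted class index/indices; ties break toward the earlier label."""
    p = np.atleast_2d(predict_proba(params, features))
    idx = p.argmax(axis=1)
    return idx[0] if np.ndim(features) == 1 else idx


def accuracy(params: ModelParameters, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(predict(params, x) == np.asarray(y)))


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature standardization fitted once on the pooled training split
    and broadcast to every client (constant features get unit scale)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


FORMAT_VERSION = 1


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Flat array as a text file with a JSON architecture sidecar."""
    path = Path(path)
    np.savetxt(path, params.flat)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "architecture": asdict(params.arch),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_params(path: str | Path) -> ModelParameters:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    arch_d = sidecar["architecture"]
    arch = Architecture(
        input_dim=arch_d["input_dim"],
        hidden_layers=tuple(arch_d["hidden_layers"]),
        n_classes=arch_d["n_classes"],
        activation=arch_d["activation"],
    )
    return ModelParameters(flat=np.loadtxt(path), arch=arch)
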