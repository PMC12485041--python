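"""Sequence-encoder models emitting C-dimensional logits.

Models here are compact fully-connected networks over the flattened input
window (channels x time), written directly in numpy with analytic
backpropagation.  That keeps every forecaster in this package small,
dependency-light and bit-reproducible under a fixed seed, which is what the
benchmark suite needs: the scientific claims are comparative (distilled
student vs. baseline student of the *same* architecture), not tied to a
particular encoder family.

The freeze contract mirrors distillation practice: a teacher is trained,
then frozen; a :class:`FrozenModel` still runs forward passes but refuses
gradient updates, and carries a parameter checksum so teacher constancy can
be asserted across an entire student training run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSpec", "MLPModel", "FrozenModel", "build_model", "freeze", "SGD", "Adam"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and initialization description of a forecaster.

    ``input_shape`` is (channels, window_len); scalar series use 1 channel.
    """

    input_shape: tuple[int, int]
    num_classes: int
    architecture: str = "mlp"
    hidden: tuple[int, ...] = (64,)
    seed: int = 0
    frontend: str = "raw"  # "raw" | "logpower" | "bandpower"
    frontend_subwindows: int = 8

    def __post_init__(self) -> None:
        ch, L = self.input_shape
        if ch < 1 or L < 1:
            raise ValueError("input_shape entries must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.architecture != "mlp":
            raise ValueError(
                f"unsupported architecture {self.architecture!r}; this package "
                "implements compact 'mlp' encoders"
            )
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden sizes must be positive")
        if self.frontend not in ("raw", "logpower", "bandpower"):
            raise ValueError(f"unknown frontend {self.frontend!r}")
        if self.frontend != "raw" and not 1 <= self.frontend_subwindows <= L // 2:
            raise ValueError("frontend_subwindows must be in [1, window length / 2]")

    @property
    def in_dim(self) -> int:
        if self.frontend in ("logpower", "bandpower"):
            return self.input_shape[0] * self.frontend_subwindows
        return self.input_shape[0] * self.input_shape[1]


class MLPModel:
    """Fully-connected tanh network: flattened window -> hidden -> C logits."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        dims = [spec.in_dim, *spec.hidden, spec.num_classes]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / (d_in + d_out))  # Glorot
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self.frozen = False
        # input standardization (set from training data; identity until then)
        self.input_mean = np.zeros(spec.in_dim)
        self.input_std = np.ones(spec.in_dim)

    def set_input_stats(self, X) -> None:
        """Record per-feature train-set mean/std, applied to every forward pass."""
        flat = self._flatten(X)
        self.input_mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        self.input_std = np.where(std > 0, std, 1.0)

    # -- forward / backward ----------------------------------------------

    def _flatten(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.spec.frontend != "raw":
            # fixed feature front-ends (no trainable parameters; gradients
            # stop at the features): per-channel log power either over equal
            # time sub-windows ("logpower") or in equal-width frequency
            # bands of the window periodogram ("bandpower")
            if X.ndim == 2:  # (n, ch*L) given flat; reshape to (n, ch, L)
                X = X.reshape(X.shape[0], *self.spec.input_shape)
            n, ch, L = X.shape
            k = self.spec.frontend_subwindows
            if self.spec.frontend == "logpower":
                trim = (L // k) * k
                sub = X[:, :, :trim].reshape(n, ch, k, trim // k)
                feat = np.mean(sub**2, axis=3)
            else:
                spec_pow = np.abs(np.fft.rfft(X, axis=2)[:, :, 1:]) ** 2  # drop DC
                nb = spec_pow.shape[2]
                trim = (nb // k) * k
                feat = np.mean(
                    spec_pow[:, :, :trim].reshape(n, ch, k, trim // k), axis=3
                )
            return np.log(feat + 1e-12).reshape(n, ch * k)
        return X.reshape(X.shape[0], -1)

    def forward(self, X, return_cache: bool = False):
        """Map a batch of input windows to a batch of C logits."""
        h = self._flatten(X)
        if h.shape[1] != self.spec.in_dim:
            raise ValueError(
                f"input has {h.shape[1]} features, model expects {self.spec.in_dim}"
            )
        h = (h - self.input_mean) / self.input_std
        cache = [h]
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < n_layers - 1:
                h = np.tanh(h)
            cache.append(h)
        if return_cache:
            return h, cache
        return h

    def __call__(self, X):
        return self.forward(X)

    def backward(self, cache, dlogits: np.ndarray):
        """Gradients of the loss w.r.t. all parameters given d loss / d logits."""
        grads_W, grads_b = [], []
        delta = np.asarray(dlogits, dtype=float)
        n_layers = len(self.weights)
        for i in range(n_layers - 1, -1, -1):
            a_prev = cache[i]
            grads_W.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (1.0 - cache[i] ** 2)
        grads_W.reverse()
        grads_b.reverse()
        return grads_W, grads_b

    # -- parameter bookkeeping -------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def checksum(self) -> str:
        """SHA-256 over the exact parameter bytes (bit-level identity)."""
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def copy(self) -> "MLPModel":
        m = MLPModel(self.spec)
        m.weights = [w.copy() for w in self.weights]
        m.biases = [b.copy() for b in self.biases]
        m.input_mean = self.input_mean.copy()
        m.input_std = self.input_std.copy()
        return m

    # -- checkpointing ----------------------------------------------------

    def save(self, path, provenance: dict | None = None) -> None:
        """Write spec + parameters + provenance to a JSON checkpoint."""
        doc = {
            "spec": {
                "input_shape": list(self.spec.input_shape),
                "num_classes": self.spec.num_classes,
                "architecture": self.spec.architecture,
                "hidden": list(self.spec.hidden),
                "seed": self.spec.seed,
                "frontend": self.spec.frontend,
                "frontend_subwindows": self.spec.frontend_subwindows,
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
            "checksum": self.checksum(),
            "provenance": provenance or {},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            doc = json.load(fh)
        s = doc["spec"]
        spec = ModelSpec(
            input_shape=tuple(s["input_shape"]),
            num_classes=s["num_classes"],
            architecture=s["architecture"],
            hidden=tuple(s["hidden"]),
            seed=s["seed"],
            frontend=s.get("frontend", "raw"),
            frontend_subwindows=s.get("frontend_subwindows", 8),
        )
        m = cls(spec)
        m.weights = [np.asarray(w, dtype=float) for w in doc["weights"]]
        m.biases = [np.asarray(b, dtype=float) for b in doc["biases"]]
        if "input_mean" in doc:
            m.input_mean = np.asarray(doc["input_mean"], dtype=float)
            m.input_std = np.asarray(doc["input_std"], dtype=float)
        return m


class FrozenModel:
    """Read-only wrapper around a trained model (the distillation teacher).

    Forward passes work as before; the parameter arrays are flagged
    immutable and a checksum is recorded at freeze time so invariance can be
    verified after any amount of student training.
    """

    def __init__(self, model: MLPModel, provenance: dict | None = None):
        self._model = model.copy()
        for p in self._model.parameters():
            p.flags.writeable = False
        self._model.input_mean.flags.writeable = False
        self._model.input_std.flags.writeable = False
        self._model.frozen = True
        self.provenance = dict(provenance or {})
        self.checksum_at_freeze = self._model.checksum()

    @property
    def spec(self) -> ModelSpec:
        return self._model.spec

    @property
    def frozen(self) -> bool:
        return True

    def forward(self, X):
        return self._model.forward(X)

    def __call__(self, X):
        return self._model.forward(X)

    def parameters(self) -> list[np.ndarray]:
        return self._model.parameters()

    def checksum(self) -> str:
        return self._model.checksum()

    def verify(self) -> bool:
        """True iff the parameters still match the freeze-time checksum."""
        return self.checksum() == self.checksum_at_freeze

    def save(self, path) -> None:
        self._model.save(path, provenance=self.provenance)


def build_model(spec: ModelSpec) -> MLPModel:
    """Construct a model from its spec; identical seeds give identical init."""
    return MLPModel(spec)


def freeze(model: MLPModel, provenance: dict | None = None) -> FrozenModel:
    """Freeze a trained model for use as a distillation teacher."""
    return FrozenModel(model, provenance=provenance)


def _check_trainable(model) -> None:
    if isinstance(model, FrozenModel) or getattr(model, "frozen", False):
        raise ValueError("cannot register frozen model parameters with an optimizer")


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, model, lr: float, momentum: float = 0.0):
        _check_trainable(model)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p) for p in model.parameters()]

    def step(self, grads_W, grads_b) -> None:
        grads = [*grads_W, *grads_b]
        for p, g, v in zip(self.model.parameters(), grads, self._vel):
            v *= self.momentum
            v += g
            p -= self.lr * v


class Adam:
    """Adam optimizer (Kingma & Ba) with standard defaults."""

    def __init__(self, model, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        _check_trainable(model)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        params = model.parameters()
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._t = 0

    def step(self, grads_W, grads_b) -> None:
        self._t += 1
        grads = [*grads_W, *grads_b]
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(self.model.parameters(), grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def make_optimizer(name: str, model, lr: float):
    name = name.lower()
    if name == "sgd":
        return SGD(model, lr)
    if name == "adam":
        return Adam(model, lr)
    raise ValueError(f"unknown optimizer {name!r}")
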