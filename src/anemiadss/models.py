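"""Class-weighted neural direction models.

Two small networks map the stacked two-timing feature rows to direction
probabilities:

* ESA — a dense feed-forward stack over the flattened two-timing input,
  emitting (P_UP, P_STAY, P_DOWN);
* IS — a recurrent (Elman) cell consuming the two timings stepwise,
  followed by a dense stack, emitting (P_UP, P_STAY).

Both use 10 hidden layers by default, rectified-linear activations, L1
weight regularization and dropout, and are trained with Adam on
class-weighted cross-entropy.  Training data are heavily dominated by
STAY, so class weights start at the inverse-ratio values
``w_c = W / (K * n_c)`` and are then iteratively adjusted until the
per-class training recalls are approximately equal (the multiplicative
update ``w_c <- w_c * (mean_recall / recall_c)**gamma``).

Everything is NumPy and fully deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import Direction, Medication
from .features import FeatureDataset, Normalizer, classes_for

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ClassWeights",
    "ProbabilityTriple",
    "DecisionModel",
    "EqualizeResult",
    "inverse_ratio_weights",
    "equalize_recalls",
    "train_model",
    "predict",
]


@dataclass(frozen=True)
class ModelConfig:
    medication: Medication = Medication.ESA
    hidden_layers: int = 10
    hidden_width: int = 16
    l1_coeff: float = 1e-5
    dropout_rate: float = 0.10
    sequence_len: int = 2
    epochs: int = 40
    batch_size: int = 512
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if self.sequence_len != 2:
            raise ValueError("models consume exactly two successive timings")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l1_coeff < 0:
            raise ValueError("l1_coeff must be non-negative")


@dataclass(frozen=True)
class ClassWeights:
    classes: tuple[str, ...]
    values: tuple[float, ...]
    provenance: str = "inverse_ratio"   # or "adjusted"

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.values):
            raise ValueError("one weight per class required")
        if any(v <= 0 for v in self.values):
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    @classmethod
    def uniform(cls, classes: Sequence[str]) -> "ClassWeights":
        return cls(tuple(classes), tuple(1.0 for _ in classes), "uniform")


@dataclass(frozen=True)
class ProbabilityTriple:
    """Direction probabilities for one occasion; p_down is None for IS."""

    p_up: float
    p_stay: float
    p_down: Optional[float] = None

    def __post_init__(self) -> None:
        total = self.p_up + self.p_stay + (self.p_down or 0.0)
        if not (abs(total - 1.0) < 1e-6):
            raise ValueError(f"probabilities must sum to 1, got {total}")


def inverse_ratio_weights(class_counts: dict[str, int]) -> ClassWeights:
    """w_c = W_total / (K * n_c): equal-count classes get equal weight and
    the weights are invariant to scaling all counts."""
    classes = tuple(class_counts)
    counts = np.asarray([class_counts[c] for c in classes], dtype=np.float64)
    if (counts <= 0).any():
        missing = [c for c, n in class_counts.items() if n <= 0]
        raise ValueError(f"classes absent from training data: {missing}")
    total = counts.sum()
    values = total / (len(classes) * counts)
    return ClassWeights(classes, tuple(float(v) for v in values), "inverse_ratio")


# --------------------------------------------------------------------------
# network internals

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Net:
    """Parameter container with Adam state; subclasses define the graph."""

    def __init__(self, cfg: ModelConfig, n_features: int, n_classes: int) -> None:
        self.cfg = cfg
        self.n_features = n_features
        self.n_classes = n_classes
        self.rng = np.random.default_rng(cfg.seed)
        self.params: list[np.ndarray] = []
        self._build()
        self._m = [np.zeros_like(p) for p in self.params]
        self._v = [np.zeros_like(p) for p in self.params]
        self._step = 0

    def _he(self, fan_in: int, shape) -> np.ndarray:
        return (self.rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    def _build(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, X: np.ndarray, train: bool = False):  # pragma: no cover
        raise NotImplementedError

    def backward(self, cache, dlogits: np.ndarray) -> list[np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def _dropout_mask(self, shape) -> np.ndarray:
        keep = 1.0 - self.cfg.dropout_rate
        return (self.rng.random(shape) < keep).astype(np.float32) / keep

    def adam_update(self, grads: list[np.ndarray]) -> None:
        self._step += 1
        lr, b1, b2, eps = self.cfg.learning_rate, 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(self.params, grads)):
            # L1 on weight matrices only (ndim 2), never on biases
            if p.ndim == 2 and self.cfg.l1_coeff > 0:
                g = g + self.cfg.l1_coeff * np.sign(p)
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self._step)
            vhat = self._v[i] / (1 - b2 ** self._step)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


class _DenseNet(_Net):
    """Feed-forward stack over the flattened two-timing input (ESA)."""

    def _build(self) -> None:
        w, L = self.cfg.hidden_width, self.cfg.hidden_layers
        dims = [2 * self.n_features] + [w] * L + [self.n_classes]
        for a, b in zip(dims, dims[1:]):
            self.params.append(self._he(a, (a, b)))
            self.params.append(np.zeros(b, dtype=np.float32))

    def forward(self, X: np.ndarray, train: bool = False):
        h = X.reshape(X.shape[0], -1).astype(np.float32)
        acts = [h]
        masks = []
        L = self.cfg.hidden_layers
        for i in range(L):
            W, b = self.params[2 * i], self.params[2 * i + 1]
            h = _relu(h @ W + b)
            if train and self.cfg.dropout_rate > 0:
                m = self._dropout_mask(h.shape)
                h = h * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(h)
        W, b = self.params[2 * L], self.params[2 * L + 1]
        logits = h @ W + b
        return logits, (acts, masks)

    def backward(self, cache, dlogits: np.ndarray) -> list[np.ndarray]:
        acts, masks = cache
        L = self.cfg.hidden_layers
        grads: list[Optional[np.ndarray]] = [None] * len(self.params)
        W_out = self.params[2 * L]
        grads[2 * L] = acts[-1].T @ dlogits
        grads[2 * L + 1] = dlogits.sum(axis=0)
        dh = dlogits @ W_out.T
        for i in range(L - 1, -1, -1):
            if masks[i] is not None:
                dh = dh * masks[i]
            dh = dh * (acts[i + 1] > 0)
            W = self.params[2 * i]
            grads[2 * i] = acts[i].T @ dh
            grads[2 * i + 1] = dh.sum(axis=0)
            dh = dh @ W.T
        return grads  # type: ignore[return-value]


class _RecurrentNet(_Net):
    """Elman cell over the two timings, then a dense stack (IS)."""

    def _build(self) -> None:
        w, L = self.cfg.hidden_width, self.cfg.hidden_layers
        d = self.n_features
        self.params.append(self._he(d, (d, w)))        # W_x
        self.params.append(self._he(w, (w, w)))        # W_h
        self.params.append(np.zeros(w, dtype=np.float32))  # b_h
        dims = [w] * L + [self.n_classes]               # L-1 dense hidden + output
        for a, b in zip(dims, dims[1:]):
            self.params.append(self._he(a, (a, b)))
            self.params.append(np.zeros(b, dtype=np.float32))

    def forward(self, X: np.ndarray, train: bool = False):
        X = X.astype(np.float32)
        W_x, W_h, b_h = self.params[0], self.params[1], self.params[2]
        x1, x2 = X[:, 0, :], X[:, 1, :]
        h1 = np.tanh(x1 @ W_x + b_h)
        h2 = np.tanh(x2 @ W_x + h1 @ W_h + b_h)
        h = h2
        acts = [h]
        masks = []
        L = self.cfg.hidden_layers
        for i in range(L - 1):
            W, b = self.params[3 + 2 * i], self.params[4 + 2 * i]
            h = _relu(h @ W + b)
            if train and self.cfg.dropout_rate > 0:
                m = self._dropout_mask(h.shape)
                h = h * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(h)
        W, b = self.params[3 + 2 * (L - 1)], self.params[4 + 2 * (L - 1)]
        logits = h @ W + b
        return logits, (x1, x2, h1, h2, acts, masks)

    def backward(self, cache, dlogits: np.ndarray) -> list[np.ndarray]:
        x1, x2, h1, h2, acts, masks = cache
        L = self.cfg.hidden_layers
        grads: list[Optional[np.ndarray]] = [None] * len(self.params)
        W_out = self.params[3 + 2 * (L - 1)]
        grads[3 + 2 * (L - 1)] = acts[-1].T @ dlogits
        grads[4 + 2 * (L - 1)] = dlogits.sum(axis=0)
        dh = dlogits @ W_out.T
        for i in range(L - 2, -1, -1):
            if masks[i] is not None:
                dh = dh * masks[i]
            dh = dh * (acts[i + 1] > 0)
            W = self.params[3 + 2 * i]
            grads[3 + 2 * i] = acts[i].T @ dh
            grads[4 + 2 * i] = dh.sum(axis=0)
            dh = dh @ W.T
        # through the recurrent cell (two unrolled steps)
        W_x, W_h = self.params[0], self.params[1]
        dz2 = dh * (1 - h2 * h2)
        gWx = x2.T @ dz2
        gWh = h1.T @ dz2
        gb = dz2.sum(axis=0)
        dh1 = dz2 @ W_h.T
        dz1 = dh1 * (1 - h1 * h1)
        gWx += x1.T @ dz1
        gb += dz1.sum(axis=0)
        grads[0], grads[1], grads[2] = gWx, gWh, gb
        return grads  # type: ignore[return-value]


@dataclass
class DecisionModel:
    """A trained direction model plus everything needed to apply it."""

    config: ModelConfig
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    net: _Net
    class_weights: ClassWeights
    normalizer: Optional[Normalizer] = None

    def predict_proba(self, ds: FeatureDataset) -> np.ndarray:
        if ds.feature_names != self.feature_names:
            raise ValueError("feature layout does not match the model's")
        logits, _ = self.net.forward(ds.X, train=False)
        return _softmax(logits.astype(np.float64))

    def save(self, path) -> str:
        payload = {
            "medication": self.config.medication.value,
            "config": {**{k: getattr(self.config, k) for k in (
                "hidden_layers", "hidden_width", "l1_coeff", "dropout_rate",
                "sequence_len", "epochs", "batch_size", "learning_rate", "seed")}},
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "class_weights": {"classes": list(self.class_weights.classes),
                              "values": list(self.class_weights.values),
                              "provenance": self.class_weights.provenance},
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
            "params": [p.tolist() for p in self.net.params],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return str(path)

    @classmethod
    def load(cls, path) -> "DecisionModel":
        with open(path) as fh:
            payload = json.load(fh)
        med = Medication(payload["medication"])
        cfg = ModelConfig(medication=med, **payload["config"])
        n_features = len(payload["feature_names"])
        n_classes = len(payload["classes"])
        net_cls = _DenseNet if med is Medication.ESA else _RecurrentNet
        net = net_cls(cfg, n_features, n_classes)
        net.params = [np.asarray(p, dtype=np.float32) for p in payload["params"]]
        cw = payload["class_weights"]
        norm = payload["normalizer"]
        return cls(
            config=cfg,
            classes=tuple(payload["classes"]),
            feature_names=tuple(payload["feature_names"]),
            net=net,
            class_weights=ClassWeights(tuple(cw["classes"]), tuple(cw["values"]),
                                       cw["provenance"]),
            normalizer=Normalizer.from_dict(norm) if norm else None,
        )


def train_model(
    config: ModelConfig,
    train: FeatureDataset,
    weights: ClassWeights,
) -> DecisionModel:
    """Train with Adam on class-weighted cross-entropy + L1.

    Deterministic given ``config.seed``.  The dataset must already be
    normalized (see :func:`anemiadss.features.apply_normalizer`)."""
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    if not train.normalized:
        raise ValueError("features must be normalized before training")
    if tuple(weights.classes) != tuple(train.classes):
        raise ValueError("class weight order must match dataset classes")
    if config.medication is not train.medication:
        raise ValueError("config medication does not match dataset")

    n_classes = len(train.classes)
    net_cls = _DenseNet if config.medication is Medication.ESA else _RecurrentNet
    net = net_cls(config, train.n_features, n_classes)

    X = train.X.astype(np.float32)
    y = train.y
    w = weights.as_array()[y].astype(np.float32)
    n = len(y)
    onehot = np.zeros((n, n_classes), dtype=np.float32)
    onehot[np.arange(n), y] = 1.0

    order_rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        order = order_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, cache = net.forward(X[idx], train=True)
            probs = _softmax(logits.astype(np.float64)).astype(np.float32)
            if not np.isfinite(probs).all():
                raise FloatingPointError(
                    "non-finite probabilities during training; "
                    "lower the learning rate or l1_coeff")
            dlogits = (probs - onehot[idx]) * w[idx, None] / len(idx)
            net.adam_update(net.backward(cache, dlogits))

    return DecisionModel(
        config=config,
        classes=train.classes,
        feature_names=train.feature_names,
        net=net,
        class_weights=weights,
    )


def predict(model: DecisionModel, ds: FeatureDataset) -> np.ndarray:
    """Per-row probabilities, columns in ``model.classes`` order."""
    return model.predict_proba(ds)


def _argmax_recalls(model: DecisionModel, ds: FeatureDataset) -> np.ndarray:
    pred = predict(model, ds).argmax(axis=1)
    recalls = np.empty(len(ds.classes))
    for c in range(len(ds.classes)):
        mask = ds.y == c
        recalls[c] = (pred[mask] == c).mean() if mask.any() else np.nan
    return recalls


@dataclass
class EqualizeResult:
    weights: ClassWeights
    recalls: np.ndarray
    spread: float
    rounds: int
    model: DecisionModel
    history: list[tuple[tuple[float, ...], float]] = field(default_factory=list)


def equalize_recalls(
    trainer: Callable[[ClassWeights], DecisionModel],
    train: FeatureDataset,
    init: ClassWeights,
    tol: float = 0.1,
    max_rounds: int = 8,
    gamma: float = 0.5,
    return_details: bool = False,
):
    """Adjust class weights until per-class training recalls are
    approximately equal (max - min <= tol), or return the best-spread
    weights found within ``max_rounds``.

    Recalls are measured with plain argmax classification: the operating
    threshold is selected only after the weights are fixed, so using it
    here would be circular.
    """
    weights = replace(init, provenance="adjusted") if init.provenance != "adjusted" else init
    best: Optional[EqualizeResult] = None
    history: list[tuple[tuple[float, ...], float]] = []
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        model = trainer(weights)
        recalls = _argmax_recalls(model, train)
        valid = recalls[~np.isnan(recalls)]
        spread = float(valid.max() - valid.min())
        history.append((weights.values, spread))
        if best is None or spread < best.spread:
            best = EqualizeResult(weights, recalls, spread, rounds, model, history)
        if spread <= tol:
            break
        mean_recall = float(valid.mean())
        new_vals = np.array([
            v * (mean_recall / max(r, 1e-3)) ** gamma if not np.isnan(r) else v
            for v, r in zip(weights.values, recalls)
        ])
        new_vals = new_vals / new_vals.mean()
        weights = ClassWeights(weights.classes, tuple(float(v) for v in new_vals),
                               "adjusted")
    assert best is not None
    if np.nanmin(best.recalls) == 0.0:
        logger.warning("a class recall is still 0 after %d rounds", rounds)
    best.history = history
    return (best.weights, best) if return_details else best.weights
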