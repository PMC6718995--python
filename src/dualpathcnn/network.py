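"""Materialize architectures into trainable networks and run the training protocol.

Training is minibatch stochastic gradient descent with momentum 0.9 and
weight decay 5e-4 on softmax cross-entropy, starting from Xavier-initialized
weights; the learning rate starts at 0.01 and is multiplied by 0.1 at the
scheduled epochs.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import archspec
from .archspec import ArchitectureSpec, audit_spec
from .nn import Network, SGDOptimizer
from .nn.layers import F32, softmax, softmax_cross_entropy

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "DivergenceError",
    "build_network",
    "train",
    "predict",
    "evaluate",
    "prepare_images",
    "save_checkpoint",
    "load_checkpoint",
    "BATCH_SIZE_PRESETS",
]

#: batch sizes used for the published experiments, by architecture role
BATCH_SIZE_PRESETS = {"sensor": 56, "reductive": 68, "deepened": 7}


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainingConfig:
    """Hyperparameters of the SGD training protocol.

    ``lr_decay_epochs`` defaults to the conventional step schedule
    {ceil(E/2), ceil(3E/4)} for E epochs when left as None.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    lr_decay_factor: float = 0.1
    lr_decay_epochs: Optional[tuple[int, ...]] = None
    epochs: int = 30
    batch_size: int = 56
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    def decay_epochs(self) -> tuple[int, ...]:
        if self.lr_decay_epochs is not None:
            return tuple(self.lr_decay_epochs)
        e = self.epochs
        return tuple(sorted({math.ceil(e / 2), math.ceil(3 * e / 4)})) if e else ()


@dataclass
class TrainedModel:
    """A network together with its config and per-epoch history.

    ``history`` rows are ``(epoch, train_loss, val_accuracy)``; validation
    accuracy is NaN when no validation set was supplied.
    """

    network: Network
    config: TrainingConfig
    history: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def spec(self) -> ArchitectureSpec:
        return self.network.spec

    @property
    def best_epoch(self) -> Optional[tuple[int, float, float]]:
        rows = [r for r in self.history if np.isfinite(r[2])]
        return max(rows, key=lambda r: r[2]) if rows else None


def build_network(spec: ArchitectureSpec, n_classes: Optional[int] = None,
                  width_multiplier: float = 1.0, seed: int = 0) -> Network:
    """Audit the spec, then materialize it with Xavier-initialized weights."""
    report = audit_spec(spec)
    if not report.ok:
        raise archspec.SpecStructureError(
            f"spec {spec.name!r} fails its shape audit:\n{report}"
        )
    return Network(spec, n_classes=n_classes, width_multiplier=width_multiplier, seed=seed)


def prepare_images(images: np.ndarray, spec: ArchitectureSpec) -> np.ndarray:
    """Cast images to float32 in [0, 1], NHWC, matching the spec input shape.

    Grayscale (n, H, W) input is tiled across the spec's channel count;
    uint8 input is scaled by 1/255.
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = np.repeat(x[..., None], spec.input_shape.channels, axis=-1)
    if x.dtype == np.uint8:
        x = x.astype(F32) / F32(255)
    return np.ascontiguousarray(x, dtype=F32)


def evaluate(network: Network, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> float:
    """Classification accuracy in evaluation mode (running batch-norm stats)."""
    x = prepare_images(images, network.spec)
    labels = np.asarray(labels)
    correct = 0
    for start in range(0, len(x), batch_size):
        probs = network.predict_proba(x[start:start + batch_size])
        correct += int((probs.argmax(axis=1) == labels[start:start + batch_size]).sum())
    return correct / len(x)


def train(network: Network, train_set: tuple[np.ndarray, np.ndarray],
          val_set: Optional[tuple[np.ndarray, np.ndarray]] = None,
          cfg: TrainingConfig = TrainingConfig(),
          verbose: bool = False) -> TrainedModel:
    """Minibatch SGD over ``cfg.epochs`` epochs; reproducible given the seed.

    ``train_set`` and ``val_set`` are ``(images, labels)`` pairs; labels must
    lie in ``0..n_classes-1``.  With ``epochs=0`` the untrained network is
    returned with an empty history.
    """
    x_train, y_train = train_set
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    y_train = np.asarray(y_train, dtype=int)
    if y_train.min() < 0 or y_train.max() >= network.n_classes:
        raise ValueError(f"labels must be in 0..{network.n_classes - 1}")
    x_train = prepare_images(x_train, network.spec)

    model = TrainedModel(network, cfg)
    if cfg.epochs == 0:
        return model

    opt = SGDOptimizer(network, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    lr = cfg.learning_rate
    decay_at = set(cfg.decay_epochs())

    for epoch in range(1, cfg.epochs + 1):
        if epoch in decay_at:
            lr *= cfg.lr_decay_factor
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = network.forward(x_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"{loss}; consider lowering the learning rate"
                )
            network.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        val_acc = (evaluate(network, *val_set) if val_set is not None
                   and len(val_set[0]) else float("nan"))
        model.history.append((epoch, float(np.mean(losses)), val_acc))
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.4g}  loss {np.mean(losses):.4f}  "
                  f"val_acc {val_acc:.4f}")
    return model


def predict(model, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax; ties go to the lowest index) and probability rows."""
    network = model.network if isinstance(model, TrainedModel) else model
    x = prepare_images(images, network.spec)
    probs = []
    for start in range(0, len(x), 64):
        probs.append(network.predict_proba(x[start:start + 64]))
    probs = np.concatenate(probs) if probs else np.zeros((0, network.n_classes))
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# Checkpoints: one .npz archive holding weights + spec + config + history

def save_checkpoint(model: TrainedModel, path) -> None:
    meta = {
        "spec_yaml": archspec.spec_to_yaml(model.spec),
        "config": asdict(model.config),
        "history": model.history,
        "n_classes": model.network.n_classes,
        "width_multiplier": model.network.width_multiplier,
        "seed": model.network.seed,
    }
    arrays = {f"state/{k}": v for k, v in model.network.state_dict().items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
    spec = archspec.load_spec(io.StringIO(meta["spec_yaml"]))
    cfg_dict = dict(meta["config"])
    if cfg_dict.get("lr_decay_epochs") is not None:
        cfg_dict["lr_decay_epochs"] = tuple(cfg_dict["lr_decay_epochs"])
    cfg = TrainingConfig(**cfg_dict)
    network = Network(spec, n_classes=meta["n_classes"],
                      width_multiplier=meta["width_multiplier"], seed=meta["seed"])
    network.load_state_dict(state)
    history = [tuple(row) for row in meta["history"]]
    return TrainedModel(network, cfg, history)
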