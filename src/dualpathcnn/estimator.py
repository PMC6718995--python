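"""scikit-learn estimator facade over the dual-path network trainer."""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .archspec import ArchitectureSpec, get_spec
from .network import TrainingConfig, build_network, predict as _predict, train as _train

__all__ = ["DualPathCNNClassifier"]


class DualPathCNNClassifier(BaseEstimator, ClassifierMixin):
    """Image classifier built from a dual-path architecture spec.

    Follows the sklearn estimator contract: hyperparameters are constructor
    arguments, ``fit(X, y)`` trains from scratch, fitted state lives in
    trailing-underscore attributes, and ``get_params``/``set_params`` work
    with sklearn model selection.

    Parameters
    ----------
    arch : str or ArchitectureSpec, default="original"
        Builtin architecture name (original, reductive, deepened,
        revised_deepened), a spec file path, or a spec object.
    width_multiplier : float, default=1.0
        Scales every filter count; the module chain is unchanged.
    learning_rate, momentum, weight_decay, lr_decay_factor, lr_decay_epochs,
    epochs, batch_size
        The SGD training protocol (see :class:`TrainingConfig`).
    random_state : int, default=0
        Seeds weight initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``y``.
    network_ : Network
        The trained network.
    history_ : list of (epoch, train_loss, val_accuracy)
        Per-epoch training history (val_accuracy is NaN without a
        validation set).
    """

    def __init__(self, arch: Union[str, ArchitectureSpec] = "original",
                 width_multiplier: float = 1.0, learning_rate: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 0.0005,
                 lr_decay_factor: float = 0.1,
                 lr_decay_epochs: Optional[tuple[int, ...]] = None,
                 epochs: int = 30, batch_size: int = 56, random_state: int = 0):
        self.arch = arch
        self.width_multiplier = width_multiplier
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_epochs = lr_decay_epochs
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _resolve_spec(self) -> ArchitectureSpec:
        if isinstance(self.arch, ArchitectureSpec):
            return self.arch
        return get_spec(self.arch)

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            weight_decay=self.weight_decay, lr_decay_factor=self.lr_decay_factor,
            lr_decay_epochs=self.lr_decay_epochs, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.random_state,
        )

    def fit(self, X, y, X_val=None, y_val=None, verbose: bool = False):
        """Train on images ``X`` (n, H, W[, C]) with integer labels ``y``.

        ``X_val``/``y_val`` optionally supply a held-out set whose accuracy
        is recorded per epoch in ``history_``.
        """
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        y_idx = np.searchsorted(self.classes_, y)
        spec = self._resolve_spec()
        network = build_network(spec, n_classes=len(self.classes_),
                                width_multiplier=self.width_multiplier,
                                seed=self.random_state)
        val_set = None
        if X_val is not None and y_val is not None and len(X_val):
            val_set = (X_val, np.searchsorted(self.classes_, np.asarray(y_val)))
        trained = _train(network, (np.asarray(X), y_idx), val_set,
                         self._config(), verbose=verbose)
        self.network_ = trained.network
        self.trained_model_ = trained
        self.history_ = trained.history
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        _, probs = _predict(self.network_, np.asarray(X))
        return probs

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        idx, _ = _predict(self.network_, np.asarray(X))
        return self.classes_[idx]
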