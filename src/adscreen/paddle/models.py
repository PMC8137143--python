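"""Sklearn-style estimators: the PADDLE CNN and the composition MLP.

Both are cross-validated ensembles: the training proteins are split into
grouped folds (all tiles of a protein stay together), one model is trained per
fold with the remaining folds as training data, and the final prediction is
the ensemble mean. Inputs and targets are standardized to mean 0 / variance 1
on the training data; predictions are destandardized.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import (Adam, BatchNorm, Conv1D, Dense, Dropout, GlobalMaxPool,
                  Network, Swish, train_network)


class _EnsembleRegressorBase(BaseEstimator, RegressorMixin):
    """Shared fit/predict machinery for the fold-ensemble predictors."""

    def _build_network(self, input_shape: tuple, rng: np.random.Generator) -> Network:
        raise NotImplementedError

    def _validate_x(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fit(self, X, y, groups=None):
        X = self._validate_x(np.asarray(X, dtype=np.float32))
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        rng = np.random.default_rng(self.random_state)

        # standardize inputs per channel and targets, on the training data
        axes = tuple(range(X.ndim - 1))
        self.x_mean_ = X.mean(axis=axes)
        self.x_std_ = X.std(axis=axes)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = float(y.mean())
        self.y_std_ = float(y.std()) or 1.0
        Xs = ((X - self.x_mean_) / self.x_std_).astype(np.float32)
        ys = (y - self.y_mean_) / self.y_std_

        if groups is not None:
            groups = np.asarray(groups)
            n_groups = np.unique(groups).size
            if n_groups < 2:
                raise ValueError("need at least 2 protein groups")
        if self.n_folds == 1:
            # single model with a held-back validation split (grouped if
            # groups are given) instead of the full cross-validated ensemble
            if groups is not None:
                uniq = np.unique(groups)
                val_groups = rng.choice(uniq, size=max(1, uniq.size // 10),
                                        replace=False)
                val_mask = np.isin(groups, val_groups)
            else:
                val_mask = rng.random(Xs.shape[0]) < 0.1
                if not val_mask.any():
                    val_mask[0] = True
            folds = [(np.flatnonzero(~val_mask), np.flatnonzero(val_mask))]
        elif groups is not None:
            n_splits = min(self.n_folds, n_groups)
            splitter = GroupKFold(n_splits=n_splits)
            folds = list(splitter.split(Xs, ys, groups))
        else:
            n_splits = min(self.n_folds, Xs.shape[0])
            splitter = KFold(n_splits=n_splits, shuffle=True,
                             random_state=int(rng.integers(2**31)))
            folds = list(splitter.split(Xs, ys))

        self.models_ = []
        self.histories_ = []
        for train_idx, val_idx in folds:
            if train_idx.size == 0 or val_idx.size == 0:
                raise ValueError("empty fold")
            net = self._build_network(Xs.shape[1:], rng)
            hist = train_network(
                net, Xs[train_idx], ys[train_idx], Xs[val_idx], ys[val_idx],
                rng=rng, lr=self.lr, max_epochs=self.max_epochs,
                batch_size=self.batch_size,
                lr_patience=self.lr_patience,
                early_stop_patience=self.early_stop_patience,
            )
            self.models_.append(net)
            self.histories_.append(hist)
        self.n_features_in_ = int(np.prod(Xs.shape[1:]))
        return self

    def _member_predictions(self, X) -> np.ndarray:
        check_is_fitted(self, "models_")
        X = self._validate_x(np.asarray(X, dtype=np.float32))
        Xs = ((X - self.x_mean_) / self.x_std_).astype(np.float32)
        preds = np.stack(
            [net.forward(Xs, training=False).ravel() for net in self.models_]
        )
        return preds * self.y_std_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        """Ensemble prediction: arithmetic mean over the fold models."""
        return self._member_predictions(X).mean(axis=0)


class PADDLERegressor(_EnsembleRegressorBase):
    """Convolutional predictor of activation Z from encoded 53-aa fragments.

    X has shape (n, 53, channels): 20 one-hot channels (noSS) or 24 with
    secondary-structure and disorder probabilities. The reference architecture
    is nine same-padded conv layers (kernel 10, 30 channels) with Swish, batch
    norm and dropout, a global max-pool over the sequence axis, and two dense
    layers of width 20; L2 penalty 1e-3, dropout 0.1, Adam at lr 1e-3 for up
    to 500 epochs with plateau LR-drop and smoothed-val early stopping.
    Smaller configurations train the same way.
    """

    def __init__(self, n_conv_layers: int = 9, channels: int = 30,
                 kernel_size: int = 10, dense_width: int = 20,
                 n_dense_layers: int = 2, dropout: float = 0.1,
                 l2: float = 1e-3, batch_norm: bool = True,
                 lr: float = 1e-3, max_epochs: int = 500, batch_size: int = 64,
                 n_folds: int = 10, lr_patience: int = 20,
                 early_stop_patience: int = 75, random_state: int = 0):
        self.n_conv_layers = n_conv_layers
        self.channels = channels
        self.kernel_size = kernel_size
        self.dense_width = dense_width
        self.n_dense_layers = n_dense_layers
        self.dropout = dropout
        self.l2 = l2
        self.batch_norm = batch_norm
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.n_folds = n_folds
        self.lr_patience = lr_patience
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    def _validate_x(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 3:
            raise ValueError("PADDLERegressor expects X of shape (n, 53, channels)")
        return X

    def _build_network(self, input_shape, rng) -> Network:
        L, c_in = input_shape
        layers: list[_nn.Layer] = []
        c = c_in
        for _ in range(self.n_conv_layers):
            layers.append(Conv1D(c, self.channels, self.kernel_size, rng))
            if self.batch_norm:
                layers.append(BatchNorm(self.channels))
            layers.append(Swish())
            if self.dropout:
                layers.append(Dropout(self.dropout, rng))
            c = self.channels
        layers.append(GlobalMaxPool())
        w = self.channels
        for _ in range(self.n_dense_layers):
            layers.append(Dense(w, self.dense_width, rng))
            if self.batch_norm:
                layers.append(BatchNorm(self.dense_width))
            layers.append(Swish())
            if self.dropout:
                layers.append(Dropout(self.dropout, rng))
            w = self.dense_width
        layers.append(Dense(w, 1, rng))
        return Network(layers, l2=self.l2)


class CompositionMLP(_EnsembleRegressorBase):
    """Amino-acid-composition baseline: order-blind MLP on 20-element
    residue-proportion vectors (three dense layers of width 40, Swish, batch
    norm, dropout 0.4, L2 1e-2, Adam at lr 1e-4 for up to 300 epochs)."""

    def __init__(self, hidden_width: int = 40, n_hidden_layers: int = 3,
                 dropout: float = 0.4, l2: float = 1e-2, batch_norm: bool = True,
                 lr: float = 1e-4, max_epochs: int = 300, batch_size: int = 64,
                 n_folds: int = 10, lr_patience: int = 20,
                 early_stop_patience: int = 75, random_state: int = 0):
        self.hidden_width = hidden_width
        self.n_hidden_layers = n_hidden_layers
        self.dropout = dropout
        self.l2 = l2
        self.batch_norm = batch_norm
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.n_folds = n_folds
        self.lr_patience = lr_patience
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    def _validate_x(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 2:
            raise ValueError("CompositionMLP expects X of shape (n, 20)")
        return X

    def _build_network(self, input_shape, rng) -> Network:
        (n_in,) = input_shape
        layers: list[_nn.Layer] = []
        w = n_in
        for _ in range(self.n_hidden_layers):
            layers.append(Dense(w, self.hidden_width, rng))
            if self.batch_norm:
                layers.append(BatchNorm(self.hidden_width))
            layers.append(Swish())
            if self.dropout:
                layers.append(Dropout(self.dropout, rng))
            w = self.hidden_width
        layers.append(Dense(w, 1, rng))
        return Network(layers, l2=self.l2)
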