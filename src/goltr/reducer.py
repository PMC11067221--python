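"""Autoencoder dimensionality reduction for sparse high-dimensional views.

Binary domain-fingerprint vectors (~14k dims in the intended workflow) and
PPI adjacency rows are compressed to dense representations (1000 dims by
default) by a symmetric autoencoder: four encoder layers and four decoder
layers with ReLU activations between them, trained to minimise mean squared
reconstruction error (binary cross-entropy optional for 0/1 inputs).

Implemented as a scikit-learn style transformer with hand-derived
backpropagation, so training is fully deterministic given ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._optim import make_optimizer
from .views import ViewMatrix


def _relu(x):
    return np.maximum(x, 0.0)


class AutoencoderReducer(TransformerMixin, BaseEstimator):
    """Reduce a view to ``target_dim`` dense features.

    Parameters
    ----------
    target_dim : int
        Width of the bottleneck (the reduced representation).
    hidden_dims : tuple of int
        Widths of the two intermediate encoder layers; the encoder is
        [n_features, hidden_dims[0], hidden_dims[1], target_dim] and the
        decoder mirrors it.  Defaults scale the published architecture
        (4096, 2048) down automatically when the input is small.
    loss : {"mse", "bce"}
        Reconstruction loss; "bce" applies a sigmoid output and expects
        inputs in {0, 1}.
    epochs, batch_size, learning_rate, optimizer, random_state
        Standard training knobs; all randomness is seeded.
    """

    def __init__(self, target_dim: int = 1000,
                 hidden_dims: tuple[int, int] | None = None,
                 loss: str = "mse", epochs: int = 100, batch_size: int = 64,
                 learning_rate: float = 1e-3, optimizer: str = "adam",
                 random_state: int = 0):
        self.target_dim = target_dim
        self.hidden_dims = hidden_dims
        self.loss = loss
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    def _widths(self, n_in: int) -> list[int]:
        if self.hidden_dims is not None:
            h1, h2 = self.hidden_dims
        else:
            h1, h2 = 4096, 2048
            while h1 >= 2 * n_in and h1 > 2 * self.target_dim:
                h1 //= 2
                h2 //= 2
        return [n_in, h1, h2, self.target_dim]

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 rows")
        n, n_in = X.shape
        if self.target_dim > n_in:
            raise ValueError("target_dim must not exceed the input width")
        widths = self._widths(n_in)
        dims = widths + widths[-2::-1]  # encoder + mirrored decoder
        rng = np.random.default_rng(self.random_state)
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases_ = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.encoder_depth_ = len(widths) - 1

        params = self.weights_ + self.biases_
        opt = make_optimizer(self.optimizer, params, self.learning_rate)
        self.loss_curve_ = [self._loss(X)]
        bs = min(self.batch_size, n)
        for _ in range(self.epochs):
            for idx in _batches(n, bs, rng):
                grads = self._grads(X[idx])
                opt.step(grads)
            self.loss_curve_.append(self._loss(X))
        if not np.isfinite(self.loss_curve_[-1]):
            raise FloatingPointError(
                f"autoencoder training diverged: loss={self.loss_curve_[-1]}"
            )
        self.n_features_in_ = n_in
        return self

    def _forward(self, X):
        acts = [X]
        h = X
        last = len(self.weights_) - 1
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            if i < last:
                h = _relu(z)
            elif self.loss == "bce":
                h = 1.0 / (1.0 + np.exp(-z))
            else:
                h = z
            acts.append(h)
        return acts

    def _loss(self, X):
        R = self._forward(X)[-1]
        if self.loss == "bce":
            eps = 1e-12
            return float(-np.mean(X * np.log(R + eps)
                                  + (1 - X) * np.log(1 - R + eps)))
        return float(np.mean((X - R) ** 2))

    def _grads(self, X):
        acts = self._forward(X)
        R = acts[-1]
        n_el = X.size
        # for both losses the output-layer delta reduces to (R - X) * scale
        delta = (R - X) * (2.0 / n_el if self.loss == "mse" else 1.0 / n_el)
        gW = [np.empty(0)] * len(self.weights_)
        gb = [np.empty(0)] * len(self.biases_)
        for i in range(len(self.weights_) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights_[i].T) * (acts[i] > 0)
        return gW + gb

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        h = X
        for i in range(self.encoder_depth_):
            z = h @ self.weights_[i] + self.biases_[i]
            h = _relu(z) if i < self.encoder_depth_ - 1 else z
        return h


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for s in range(0, n, batch_size):
        yield order[s:s + batch_size]


def train_reducer(view: ViewMatrix, target_dim: int, seed: int = 0,
                  **settings) -> AutoencoderReducer:
    """Fit an :class:`AutoencoderReducer` on a view's feature matrix."""
    model = AutoencoderReducer(target_dim=target_dim, random_state=seed,
                               **settings)
    return model.fit(view.values)


def reduce_view(model: AutoencoderReducer, view: ViewMatrix) -> ViewMatrix:
    """Apply a trained reducer's encoder to a view."""
    return ViewMatrix(f"{view.name}_reduced", view.roster,
                      model.transform(view.values))
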