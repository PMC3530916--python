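"""Single-hidden-layer feedforward network trained by backpropagation.

The classifier is a 31-unit (by default) single hidden layer with logistic
activations in both layers, trained on cross-entropy by full-batch
gradient descent (optionally mini-batches).  Overfitting is controlled by
early stopping with a validation partition: after every epoch the
validation loss is measured, and training stops once it has not improved
for ``patience`` epochs; the weights from the best-validation epoch are
restored.

Determinism: initialization and any mini-batch shuffling derive from the
seed, so identical data + seed give bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_X_y

from .errors import ConfigurationError, TrainingDivergedError

_EPS = 1e-12


@dataclass(frozen=True)
class ANNConfig:
    hidden_units: int = 31
    learning_rate: float = 0.01
    max_epochs: int = 500
    patience: int = 20
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if not self.patience < self.max_epochs:
            raise ConfigurationError("patience must be < max_epochs")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


def init_network(n_inputs: int, cfg: ANNConfig = ANNConfig(), rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Weights drawn uniformly from +-1/sqrt(fan_in) per layer; biases zero."""
    if n_inputs < 1:
        raise ConfigurationError("n_inputs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden_units
    lim1 = 1.0 / np.sqrt(n_inputs)
    lim2 = 1.0 / np.sqrt(h)
    return {
        "W1": rng.uniform(-lim1, lim1, size=(n_inputs, h)),
        "b1": np.zeros(h),
        "W2": rng.uniform(-lim2, lim2, size=h),
        "b2": np.zeros(1),
    }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(weights: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Probability of the positive class for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights["W1"].shape[0]:
        raise ConfigurationError(
            f"input has {X.shape[1]} features; network expects {weights['W1'].shape[0]}"
        )
    a1 = _sigmoid(X @ weights["W1"] + weights["b1"])
    return _sigmoid(a1 @ weights["W2"] + weights["b2"][0])


def predict_proba(weights: dict[str, np.ndarray], x: np.ndarray) -> float | np.ndarray:
    """Scalar probability for a single vector, array for a matrix."""
    x = np.asarray(x, dtype=float)
    p = forward(weights, x)
    return float(p[0]) if x.ndim == 1 else p


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _gradients(weights, X, y):
    a1 = _sigmoid(X @ weights["W1"] + weights["b1"])
    p = _sigmoid(a1 @ weights["W2"] + weights["b2"][0])
    n = X.shape[0]
    d2 = (p - y) / n  # d(loss)/d(z2) for logistic + cross-entropy
    gW2 = a1.T @ d2
    gb2 = np.array([d2.sum()])
    d1 = np.outer(d2, weights["W2"]) * a1 * (1.0 - a1)
    gW1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


class NeuralNetClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier: one logistic hidden layer, logistic output.

    Parameters mirror :class:`ANNConfig`.  ``fit`` accepts an optional
    validation set for early stopping; without one it trains for
    ``max_epochs``.

    Attributes
    ----------
    weights_ : dict of arrays W1 (d,h), b1 (h,), W2 (h,), b2 (1,)
    best_epoch_ : epoch whose weights were kept (1-based)
    best_val_loss_ : validation loss at that epoch (None without validation)
    n_epochs_run_ : epochs actually executed
    history_ : per-epoch (train loss, validation loss or nan)
    """

    def __init__(self, hidden_units: int = 31, learning_rate: float = 0.01,
                 max_epochs: int = 500, patience: int = 20,
                 batch_size: int | None = None, seed: int = 0):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed

    def _config(self) -> ANNConfig:
        return ANNConfig(self.hidden_units, self.learning_rate, self.max_epochs,
                         self.patience, self.batch_size, self.seed)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ConfigurationError("labels must be binary 0/1")
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        weights = init_network(X.shape[1], cfg, rng)
        use_val = X_val is not None and y_val is not None
        if use_val:
            X_val = check_array(X_val)
            y_val = np.asarray(y_val, dtype=float)

        best = {k: v.copy() for k, v in weights.items()}
        best_loss = np.inf
        best_epoch = 0
        since_improvement = 0
        history = []
        n = X.shape[0]
        epochs_run = 0
        for epoch in range(1, cfg.max_epochs + 1):
            epochs_run = epoch
            if cfg.batch_size is None:
                batches = [np.arange(n)]
            else:
                order = rng.permutation(n)
                batches = [order[i : i + cfg.batch_size] for i in range(0, n, cfg.batch_size)]
            for idx in batches:
                grads = _gradients(weights, X[idx], y[idx])
                for k in weights:
                    weights[k] = weights[k] - cfg.learning_rate * grads[k]
            train_loss = cross_entropy(forward(weights, X), y)
            if not np.isfinite(train_loss):
                raise TrainingDivergedError(epoch, cfg.learning_rate)
            val_loss = np.nan
            if use_val:
                val_loss = cross_entropy(forward(weights, X_val), y_val)
                if val_loss < best_loss:
                    best_loss = val_loss
                    best = {k: v.copy() for k, v in weights.items()}
                    best_epoch = epoch
                    since_improvement = 0
                else:
                    since_improvement += 1
            history.append((train_loss, val_loss))
            if use_val and since_improvement >= cfg.patience:
                break

        if use_val:
            self.weights_ = best
            self.best_epoch_ = best_epoch
            self.best_val_loss_ = best_loss
        else:
            self.weights_ = weights
            self.best_epoch_ = epochs_run
            self.best_val_loss_ = None
        self.n_epochs_run_ = epochs_run
        self.history_ = np.array(history)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        p = forward(self.weights_, check_array(X))
        return np.column_stack([1.0 - p, p])

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the positive class, one per row."""
        return forward(self.weights_, check_array(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.decision_scores(X) >= threshold).astype(int)


def train(X_train, y_train, X_val, y_val, cfg: ANNConfig = ANNConfig()) -> NeuralNetClassifier:
    """Functional wrapper: fit a network with validation early stopping."""
    net = NeuralNetClassifier(**cfg.__dict__)
    return net.fit(X_train, y_train, X_val, y_val)
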