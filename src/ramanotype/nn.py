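"""From-scratch multilayer perceptron for spectral classification/regression.

Feedforward network with 1–2 ReLU hidden layers trained by backpropagation
with the ADAM optimizer (defaults lr = 0.001, β₁ = 0.9, β₂ = 0.999,
ε = 1e-8), inverted-dropout regularization on the hidden activations, and
early stopping on validation loss with best-weight restoration.  The
classification head is softmax trained with categorical cross-entropy; the
regression head is ReLU (concentrations are nonnegative) trained with mean
squared error.

Also provides the two data-handling steps the spectral models need:
seeded train/validation/test splitting (largest-remainder rounding,
optionally stratified by class) and sliding-window spectral variable
selection — a 62-point window stepped 2 points at a time across the axis,
keeping the window with the lowest validation error.  Everything is pure
numpy and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

_CCE_EPS = 1e-12  # probability clip so -log p(true) stays finite


# ------------------------------------------------------------- primitives


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cce_loss(probabilities: np.ndarray, targets_onehot: np.ndarray) -> float:
    """Categorical cross-entropy: mean over samples of −log p(true class)."""
    P = np.clip(np.atleast_2d(probabilities), _CCE_EPS, 1.0)
    Y = np.atleast_2d(targets_onehot)
    return float(-np.mean(np.sum(Y * np.log(P), axis=1)))


def mse_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((np.ravel(y_hat) - np.ravel(y)) ** 2))


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted dropout mask: zeros w.p. ``rate``, survivors scaled 1/(1−rate)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    if rate == 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


@dataclass
class AdamState:
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)
    t: int = 0


def adam_init(params: list[np.ndarray]) -> AdamState:
    return AdamState(m=[np.zeros_like(p) for p in params],
                     v=[np.zeros_like(p) for p in params])


def adam_step(
    params: list[np.ndarray], grads: list[np.ndarray], state: AdamState,
    lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
) -> tuple[list[np.ndarray], AdamState]:
    """One bias-corrected ADAM update, in place on ``params``."""
    state.t += 1
    t = state.t
    for i, (p, g) in enumerate(zip(params, grads)):
        state.m[i] = beta1 * state.m[i] + (1 - beta1) * g
        state.v[i] = beta2 * state.v[i] + (1 - beta2) * g**2
        m_hat = state.m[i] / (1 - beta1**t)
        v_hat = state.v[i] / (1 - beta2**t)
        p -= lr * m_hat / (np.sqrt(v_hat) + eps)
    return params, state


def he_uniform(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    """He-uniform weight draw, the standard initialization for ReLU layers."""
    limit = np.sqrt(6.0 / n_in)
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# ----------------------------------------------------------------- network


class _BaseMLP(BaseEstimator):
    """Shared machinery; use :class:`MLPClassifier` / :class:`MLPRegressor`."""

    _head: str  # "softmax" or "relu"

    def __init__(
        self,
        hidden_layer_sizes=(64,),
        dropout: float = 0.0,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        max_epochs: int = 1000,
        patience: int = 50,
        batch_size: int | None = None,
        random_state: int | None = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.random_state = random_state

    # -- architecture ------------------------------------------------------

    def _init_network(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        sizes = [n_in, *self.hidden_layer_sizes, n_out]
        if not 1 <= len(self.hidden_layer_sizes) <= 2:
            raise ValueError("1 or 2 hidden layers supported")
        if any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layers need at least 1 neuron")
        self.weights_ = [he_uniform(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.biases_ = [np.zeros(b) for b in sizes[1:]]

    @property
    def topology_(self) -> str:
        sizes = [self.weights_[0].shape[0]] + [W.shape[1] for W in self.weights_]
        return "-".join(str(s) for s in sizes)

    # -- forward / backward ------------------------------------------------

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None):
        """Network output for X; dropout masks are drawn only when training."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights_[0].shape[0]:
            raise ValueError(
                f"expected {self.weights_[0].shape[0]} inputs, got {X.shape[1]}"
            )
        out, _ = self._forward_cached(X, training=training, rng=rng)
        return out

    def _forward_cached(self, X, training, rng):
        cache = {"a": [X], "z": [], "masks": []}
        A = X
        n_layers = len(self.weights_)
        for layer, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            Z = A @ W + b
            cache["z"].append(Z)
            if layer < n_layers - 1:
                A = relu(Z)
                if training and self.dropout > 0:
                    mask = dropout_mask(A.shape, self.dropout, rng)
                    A = A * mask
                else:
                    mask = None
                cache["masks"].append(mask)
            else:
                A = softmax(Z) if self._head == "softmax" else relu(Z)
            cache["a"].append(A)
        return A, cache

    def _loss(self, out, Y):
        if self._head == "softmax":
            return cce_loss(out, Y)
        return mse_loss(out, Y)

    def _backward(self, cache, Y):
        """Analytic gradients of the batch loss w.r.t. every weight/bias."""
        out = cache["a"][-1]
        n = out.shape[0]
        if self._head == "softmax":
            # d CCE/d z for softmax output (with the epsilon clip inactive)
            dZ = (out - Y) / n
        else:
            y_hat = np.ravel(out)
            dZ = (2.0 * (y_hat - np.ravel(Y)) / n)[:, None] * (cache["z"][-1] > 0)
        grads_W, grads_b = [], []
        for layer in range(len(self.weights_) - 1, -1, -1):
            A_prev = cache["a"][layer]
            grads_W.append(A_prev.T @ dZ)
            grads_b.append(dZ.sum(axis=0))
            if layer > 0:
                dA = dZ @ self.weights_[layer].T
                mask = cache["masks"][layer - 1]
                if mask is not None:
                    dA = dA * mask
                dZ = dA * (cache["z"][layer - 1] > 0)
        return grads_W[::-1], grads_b[::-1]

    def backprop_gradients(self, X, Y, training: bool = False,
                           rng: np.random.Generator | None = None):
        """Gradients of the loss on (X, Y); deterministic when not training."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, cache = self._forward_cached(X, training=training, rng=rng)
        return self._backward(cache, Y)

    # -- training loop -----------------------------------------------------

    def _train(self, X, Y, X_val, Y_val):
        rng = np.random.default_rng(self.random_state)
        n_out = Y.shape[1] if Y.ndim == 2 else 1
        self._init_network(X.shape[1], n_out, rng)
        params = self.weights_ + self.biases_
        state = adam_init(params)

        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        waiting = 0
        history = []
        n = X.shape[0]
        batch = self.batch_size or n
        Y2 = Y if Y.ndim == 2 else Y[:, None]
        Yv2 = Y_val if Y_val.ndim == 2 else Y_val[:, None]

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n) if batch < n else np.arange(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                _, cache = self._forward_cached(X[idx], training=True, rng=rng)
                gW, gb = self._backward(cache, Y2[idx])
                adam_step(params, gW + gb, state, self.learning_rate,
                          self.beta1, self.beta2, self.eps)

            train_loss = self._loss(self.forward(X), Y2)
            val_loss = self._loss(self.forward(X_val), Yv2)
            history.append((train_loss, val_loss))
            if val_loss < best_loss:
                best_loss = val_loss
                best_weights = (copy.deepcopy(self.weights_), copy.deepcopy(self.biases_))
                best_epoch = epoch
                waiting = 0
            else:
                waiting += 1
                if waiting > self.patience:
                    break

        if best_weights is not None:
            self.weights_, self.biases_ = best_weights
        self.history_ = np.array(history)
        self.stopped_epoch_ = len(history)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        return self


class MLPClassifier(ClassifierMixin, _BaseMLP):
    """Softmax/CCE classifier head over the shared MLP machinery.

    ``fit`` accepts an explicit validation set for early stopping; without
    one, training loss is monitored instead.
    """

    _head = "softmax"

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Y = self._onehot(y)
        if X_val is None:
            X_val, Y_val = X, Y
        else:
            X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
            Y_val = self._onehot(np.asarray(y_val))
        return self._train(X, Y, X_val, Y_val)

    def _onehot(self, y):
        idx = np.searchsorted(self.classes_, y)
        Y = np.zeros((y.size, self.classes_.size))
        Y[np.arange(y.size), idx] = 1.0
        return Y

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        return self.forward(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def test_loss(self, X, y):
        return cce_loss(self.predict_proba(X), self._onehot(np.asarray(y)))


class MLPRegressor(RegressorMixin, _BaseMLP):
    """ReLU-output/MSE regression head (predictions are nonnegative)."""

    _head = "relu"

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X_val is None:
            X_val, y_val = X, y
        else:
            X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
            y_val = np.asarray(y_val, dtype=float).ravel()
        return self._train(X, y, X_val, y_val)

    def predict(self, X):
        check_is_fitted(self, "weights_")
        return self.forward(X).ravel()


# ----------------------------------------------------- splits and windows


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (must sum to 1), seed, stratify flag."""

    fractions: tuple[float, ...] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _largest_remainder(n: int, fractions) -> np.ndarray:
    exact = np.asarray(fractions) * n
    sizes = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - sizes), kind="stable")[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes


def split_data(n: int, spec: SplitSpec, labels=None) -> tuple[np.ndarray, ...]:
    """Disjoint, exhaustive, seeded index splits with largest-remainder sizes.

    With ``spec.stratify`` and ``labels`` given, the rounding is applied per
    class so every split mirrors the class balance.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.fractions)
    if spec.stratify and labels is not None:
        labels = np.asarray(labels)
        parts: list[list[int]] = [[] for _ in range(k)]
        for label in np.unique(labels):
            idx = np.where(labels == label)[0]
            rng.shuffle(idx)
            sizes = _largest_remainder(idx.size, spec.fractions)
            start = 0
            for j, s in enumerate(sizes):
                parts[j].extend(idx[start : start + s])
                start += s
        out = []
        for part in parts:
            arr = np.array(sorted(part), dtype=int)
            out.append(arr)
        splits = tuple(out)
    else:
        idx = rng.permutation(n)
        sizes = _largest_remainder(n, spec.fractions)
        bounds = np.cumsum(sizes)[:-1]
        splits = tuple(np.sort(part) for part in np.split(idx, bounds))
    for j, frac in enumerate(spec.fractions):
        if frac > 0 and splits[j].size == 0:
            raise ValueError(f"split {j} (fraction {frac}) is empty at n={n}")
    return splits


def sliding_window_selection(
    X: np.ndarray, y: np.ndarray, evaluator, window: int = 62, step: int = 2,
) -> tuple[int, int]:
    """Scan fixed-width spectral windows; keep the one with lowest error.

    ``evaluator(X_window, y) -> float`` scores a candidate window (lower is
    better); ties go to the leftmost window.  Returns the half-open index
    range (start, start + window).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if window > p:
        raise ValueError(f"window {window} exceeds {p} spectral points")
    best_err, best_start = np.inf, 0
    for start in range(0, p - window + 1, step):
        err = float(evaluator(X[:, start : start + window], y))
        if err < best_err:
            best_err, best_start = err, start
    return best_start, best_start + window


def n_windows(p: int, window: int = 62, step: int = 2) -> int:
    """Number of candidate windows scanned: floor((p − window)/step) + 1."""
    if window > p:
        raise ValueError("window exceeds spectrum length")
    return (p - window) // step + 1


# ------------------------------------------------------ hyperparameter grid


def sample_config(rng: np.random.Generator) -> dict:
    """Draw one hyperparameter combination from the search ranges:
    dropout 0–0.9, 1–2 hidden layers, 2–250 neurons per layer."""
    n_layers = int(rng.integers(1, 3))
    hidden = tuple(int(rng.integers(2, 251)) for _ in range(n_layers))
    return {
        "hidden_layer_sizes": hidden,
        "dropout": float(np.round(rng.uniform(0.0, 0.9), 2)),
    }


def hyperparameter_search(
    X_train, y_train, X_val, y_val, X_test, y_test,
    n_trials: int = 50, seed: int = 0, task: str = "classification",
    max_epochs: int = 400, patience: int = 40,
) -> pd.DataFrame:
    """Random search over MLP configurations; one row per trained trial.

    Columns mirror a network-selection table: topology "in-hidden-out",
    dropout, stopped epoch, test accuracy (%) and test CCE loss for
    classification (test r and RMSE for regression).  Rows are ranked by
    (accuracy desc, test loss asc); no trial is dropped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        cfg = sample_config(rng)
        trial_seed = int(rng.integers(0, 2**31 - 1))
        cls = MLPClassifier if task == "classification" else MLPRegressor
        model = cls(random_state=trial_seed, max_epochs=max_epochs,
                    patience=patience, **cfg)
        model.fit(X_train, y_train, X_val, y_val)
        row = {
            "trial": trial,
            "topology": model.topology_,
            "dropout": cfg["dropout"],
            "epoch": model.stopped_epoch_,
        }
        if task == "classification":
            row["accuracy_pct"] = 100.0 * model.score(X_test, y_test)
            row["test_loss"] = model.test_loss(X_test, y_test)
        else:
            pred = model.predict(X_test)
            y_t = np.asarray(y_test, dtype=float)
            sd = np.std(pred)
            row["r"] = float(np.corrcoef(y_t, pred)[0, 1]) if sd > 0 else 0.0
            row["rmse"] = float(np.sqrt(np.mean((y_t - pred) ** 2)))
            row["test_loss"] = row["rmse"] ** 2
        row["seed"] = trial_seed
        rows.append(row)
    table = pd.DataFrame(rows)
    by = ["accuracy_pct", "test_loss"] if task == "classification" else ["r", "test_loss"]
    table = table.sort_values([by[0], by[1]], ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)
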