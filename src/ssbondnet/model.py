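"""The disulfide-bond classifier.

A small fully connected network on the 45 pairwise-distance features:
45 -> 128 -> 32 -> 1 with ReLU hidden activations and a logistic output
score in (0, 1).  Training is plain stochastic gradient descent on binary
cross-entropy, 10 epochs at learning rate 0.01 with mini-batches of 100 —
small enough that a hand-rolled numpy implementation is both transparent
and fast, and fully deterministic for a fixed seed.

Because the two residues of a pair have no intrinsic order, every training
sample is presented in both orientations (the 45-vector permutation induced
by swapping the residue blocks) and prediction averages the two orientation
scores, making the classifier exactly symmetric under pair-order swap.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import N_FEATURES, as_feature_array, swap_pair_order

__all__ = [
    "DisulfideBondClassifier",
    "ModelFormatError",
    "train",
    "score",
    "classify",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised when a saved model file is unreadable or inconsistent."""


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DisulfideBondClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward binary classifier for residue-pair distance features.

    Parameters
    ----------
    hidden_sizes : tuple of int, default (128, 32)
        Hidden layer widths; the full architecture is
        45 -> hidden_sizes... -> 1.
    epochs : int, default 10
        Passes over the (orientation-augmented) training set.
    learning_rate : float, default 0.01
        SGD step size.
    batch_size : int, default 100
        Mini-batch size.
    threshold : float, default 0.5
        Score at or above which a pair is called bonded.
    symmetrize : bool, default True
        Train on both pair orientations and average orientation scores at
        prediction time.  Requires 45 input features.
    random_state : int, default 0
        Seed for weight initialisation and epoch shuffling.

    Attributes
    ----------
    weights_, biases_ : lists of ndarrays, one per layer.
    training_log_ : list of dicts with per-epoch mean loss and accuracy.
    loss_curve_ : list of per-epoch mean losses.
    classes_ : ndarray [0, 1].
    """

    def __init__(self, hidden_sizes=(128, 32), epochs=10, learning_rate=0.01,
                 batch_size=100, threshold=0.5, symmetrize=True, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.threshold = threshold
        self.symmetrize = symmetrize
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(f"labels must be 0/1, got {classes}")
        if self.symmetrize and X.shape[1] != N_FEATURES:
            raise ValueError(
                f"symmetrize=True requires {N_FEATURES} distance features, "
                f"got {X.shape[1]}")
        self.classes_ = classes.astype(int)
        self.n_features_in_ = X.shape[1]

        if self.symmetrize:
            X = np.vstack([X, swap_pair_order(X)])
            y = np.concatenate([y, y])

        rng = np.random.default_rng(self.random_state)
        sizes = [self.n_features_in_, *self.hidden_sizes, 1]
        self.weights_ = []
        self.biases_ = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / fan_in)
            self.weights_.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))

        n = X.shape[0]
        eps = 1e-12
        self.training_log_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                acts, p = self._forward(xb)
                pc = np.clip(p, eps, 1.0 - eps)
                losses.append(float(np.mean(
                    -yb * np.log(pc) - (1 - yb) * np.log(1 - pc))) * len(idx))
                correct += int(np.sum((p >= self.threshold) == (yb == 1)))
                self._sgd_step(acts, p, yb)
            self.training_log_.append({
                "epoch": epoch + 1,
                "loss": sum(losses) / n,
                "accuracy": correct / n,
            })
        self.loss_curve_ = [e["loss"] for e in self.training_log_]
        return self

    def _forward(self, X):
        """Returns ([input and hidden activations], output probabilities)."""
        acts = [X]
        a = X
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        z = acts[-1] @ self.weights_[-1] + self.biases_[-1]
        return acts, _sigmoid(z[:, 0])

    def _sgd_step(self, acts, p, y):
        m = len(y)
        delta = ((p - y) / m)[:, None]  # d(mean BCE)/dz at the logistic output
        grads_w = []
        grads_b = []
        for layer in range(len(self.weights_) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights_[layer].T) * (acts[layer] > 0)
        for W, b, gw, gb in zip(self.weights_, self.biases_,
                                grads_w[::-1], grads_b[::-1]):
            W -= self.learning_rate * gw
            b -= self.learning_rate * gb

    # -------------------------------------------------------------- predict

    def _scores(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        _, p = self._forward(X)
        if self.symmetrize:
            _, p_swapped = self._forward(swap_pair_order(X))
            p = 0.5 * (p + p_swapped)
        return p

    def predict_proba(self, X):
        p = self._scores(X)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X):
        return self._scores(X)

    def predict(self, X):
        return (self._scores(X) >= self.threshold).astype(int)


# ------------------------------------------------------- functional wrappers

def train(dataset, **config) -> DisulfideBondClassifier:
    """Train a classifier on a LabelledDataset's training split."""
    clf = DisulfideBondClassifier(**config)
    return clf.fit(dataset.X_train, dataset.y_train)


def score(model: DisulfideBondClassifier, f) -> float:
    """Bond score in [0, 1] of a single distance feature."""
    return float(model._scores(as_feature_array(f)[None, :])[0])


def classify(model: DisulfideBondClassifier, f) -> str:
    """Hard call at the model threshold: 'bonded' or 'nonbonded'."""
    return "bonded" if score(model, f) >= model.threshold else "nonbonded"


# ----------------------------------------------------------- serialization

def save_model(model: DisulfideBondClassifier, path) -> None:
    """Save architecture, hyperparameters and weights as JSON.

    Floats are stored via Python's repr round-trip, so reloaded scores are
    bit-identical.
    """
    check_is_fitted(model, "weights_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "n_features_in": int(model.n_features_in_),
        "weights": [w.tolist() for w in model.weights_],
        "biases": [b.tolist() for b in model.biases_],
        "training_log": model.training_log_,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> DisulfideBondClassifier:
    """Load a model saved by :func:`save_model`, validating shapes."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format {payload.get('format_version')!r}")
    params = dict(payload["params"])
    params["hidden_sizes"] = tuple(params["hidden_sizes"])
    model = DisulfideBondClassifier(**params)
    model.n_features_in_ = int(payload["n_features_in"])
    model.classes_ = np.array([0, 1])
    sizes = [model.n_features_in_, *model.hidden_sizes, 1]
    weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
    biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
    expected = list(zip(sizes[:-1], sizes[1:]))
    got = [w.shape for w in weights]
    if got != expected or [b.shape[0] for b in biases] != [s for _, s in expected]:
        raise ModelFormatError(
            f"weight shapes {got} inconsistent with architecture {sizes}")
    model.weights_ = weights
    model.biases_ = biases
    model.training_log_ = payload.get("training_log", [])
    model.loss_curve_ = [e["loss"] for e in model.training_log_]
    return model
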