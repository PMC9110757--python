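"""Classifiers over the embedding features.

The primary model is a soft-margin SVM with the radial basis function
kernel kappa(e_i, e_j) = exp(-gamma ||e_i - e_j||^2), with the cost c and
kernel width gamma selected by an exhaustive log2 grid search (c over
2^-5..2^15 in exponent steps of 2, gamma over 2^-15..2^-5 in steps of 1).
Two further models are provided for comparison: a small 1-D convolutional
network trained by SGD on binary cross-entropy, and a gain-ratio decision
tree in the C4.5 family.

The SVM wraps scikit-learn's SVC; the CNN and tree are self-contained
numpy implementations (both deterministic under a fixed seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateLabelsError, InvalidInputError

__all__ = [
    "rbf_kernel",
    "GridSpec",
    "GridSearchResult",
    "SVMClassifier",
    "train_svm",
    "grid_search",
    "bce_loss",
    "CNNClassifier",
    "train_cnn",
    "gain_ratio",
    "GainRatioTreeClassifier",
    "predict",
]


def rbf_kernel(ei: np.ndarray, ej: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||ei - ej||^2); symmetric, in (0, 1] for gamma >= 0."""
    ei = np.asarray(ei, dtype=float)
    ej = np.asarray(ej, dtype=float)
    if ei.shape != ej.shape:
        raise InvalidInputError(
            f"dimension mismatch: {ei.shape} vs {ej.shape}"
        )
    if gamma < 0:
        raise InvalidInputError(f"gamma must be >= 0, got {gamma}")
    diff = ei - ej
    return float(np.exp(-gamma * float(diff @ diff)))


def _check_training_inputs(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("features must be 2-D and aligned with labels")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training data holds a single class")
    return X, y


class SVMClassifier:
    """RBF-kernel soft-margin SVM with real-valued decision scores.

    ``gamma`` may be a positive number or ``"scale"`` (1 / (dim * feature
    variance), the scale-adaptive convention).  With ``standardize=True``
    a per-feature z-score transform is fitted on the training data, so the
    kernel width is comparable across embedding tables of different
    magnitudes.
    """

    kind = "svm"

    def __init__(
        self,
        c: float = 2.0**4,
        gamma: float | str = 2.0**-5,
        seed: int = 0,
        standardize: bool = False,
    ):
        if c <= 0:
            raise InvalidInputError(f"need c > 0, got c={c}")
        if not (gamma == "scale" or (isinstance(gamma, (int, float)) and gamma > 0)):
            raise InvalidInputError(f"gamma must be > 0 or 'scale', got {gamma}")
        self.c = c
        self.gamma = gamma
        self.seed = seed
        self.standardize = standardize
        self._svc: SVC | None = None
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None
        self.n_features_in_: int | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self._mu is None:
            return X
        return (X - self._mu) / self._sigma

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "SVMClassifier":
        X, y = _check_training_inputs(features, labels)
        if self.standardize:
            self._mu = X.mean(axis=0)
            sigma = X.std(axis=0)
            self._sigma = np.where(sigma > 0, sigma, 1.0)
        self._svc = SVC(
            C=self.c, gamma=self.gamma, kernel="rbf", random_state=self.seed
        )
        self._svc.fit(self._transform(X), y)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise InvalidInputError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected features of dimension {self.n_features_in_}"
            )
        return self._transform(X)

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        """Signed margin distances; threshold at 0 gives the hard labels."""
        return self._svc.decision_function(self._check_fitted(features))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.decision_scores(features) > 0).astype(int)


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    c: float = 2.0**4,
    gamma: float = 2.0**-5,
    seed: int = 0,
) -> SVMClassifier:
    """Fit an RBF SVM at fixed (c, gamma)."""
    return SVMClassifier(c=c, gamma=gamma, seed=seed).fit(features, labels)


@dataclass
class GridSpec:
    """Log-base-2 search grid for the SVM cost c and kernel width gamma."""

    c_exponents: Sequence[int] = tuple(range(-5, 16, 2))
    gamma_exponents: Sequence[int] = tuple(range(-15, -4, 1))
    base: float = 2.0

    def __post_init__(self) -> None:
        if not self.c_exponents or not self.gamma_exponents:
            raise InvalidInputError("grid exponent ranges must be non-empty")
        if self.base <= 1:
            raise InvalidInputError("grid base must exceed 1")

    @property
    def c_values(self) -> list[float]:
        return [self.base**e for e in self.c_exponents]

    @property
    def gamma_values(self) -> list[float]:
        return [self.base**e for e in self.gamma_exponents]


@dataclass
class GridSearchResult:
    best_c: float
    best_gamma: float
    best_score: float
    table: pd.DataFrame  # columns c_exp, gamma_exp, c, gamma, mean_score


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    grid: GridSpec | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (c, gamma) search by mean stratified-CV accuracy.

    Ties are broken toward the smaller c, then the smaller gamma.  The
    full score table is returned so the search surface can be plotted.
    """
    grid = grid or GridSpec()
    X, y = _check_training_inputs(features, labels)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    rows = []
    best: tuple[float, float, float] | None = None  # (score, c, gamma)
    for c_exp in sorted(grid.c_exponents):
        for g_exp in sorted(grid.gamma_exponents):
            c = grid.base**c_exp
            gamma = grid.base**g_exp
            accs = []
            for train_idx, test_idx in folds:
                model = SVMClassifier(c=c, gamma=gamma, seed=seed)
                model.fit(X[train_idx], y[train_idx])
                accs.append(
                    float((model.predict(X[test_idx]) == y[test_idx]).mean())
                )
            score = float(np.mean(accs))
            rows.append(
                {
                    "c_exp": c_exp,
                    "gamma_exp": g_exp,
                    "c": c,
                    "gamma": gamma,
                    "mean_score": score,
                }
            )
            if best is None or score > best[0]:
                best = (score, c, gamma)
    assert best is not None
    return GridSearchResult(
        best_c=best[1],
        best_gamma=best[2],
        best_score=best[0],
        table=pd.DataFrame(rows),
    )


def bce_loss(
    labels: np.ndarray, predictions: np.ndarray, eps: float = 1e-12
) -> float:
    """Mean binary cross-entropy, with predictions clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=float)
    h = np.asarray(predictions, dtype=float)
    if y.shape != h.shape:
        raise InvalidInputError(
            f"labels and predictions differ in length: {y.shape} vs {h.shape}"
        )
    h = np.clip(h, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(h) + (1.0 - y) * np.log(1.0 - h)))


class CNNClassifier:
    """Small 1-D convolutional network trained by SGD on cross-entropy.

    Architecture: one convolution layer (``filters`` kernels of width
    ``width``) over the concatenated feature vector, ReLU, non-overlapping
    max-pooling, inverted dropout, then a dense layer with a sigmoid
    output.  Written directly in numpy with manual backpropagation;
    deterministic under a fixed seed.
    """

    kind = "cnn"

    def __init__(
        self,
        learning_rate: float = 5e-2,
        epochs: int = 150,
        batch_size: int = 16,
        filters: int = 32,
        width: int = 5,
        pool: int = 2,
        dropout: float = 0.5,
        seed: int = 0,
    ):
        if learning_rate <= 0 or epochs < 0 or batch_size < 1:
            raise InvalidInputError("hyperparameters must be positive")
        if not 0 <= dropout < 1:
            raise InvalidInputError("dropout must lie in [0, 1)")
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.filters = filters
        self.width = width
        self.pool = pool
        self.dropout = dropout
        self.seed = seed
        self.n_features_in_: int | None = None

    def _forward(
        self, X: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, dict]:
        win = np.lib.stride_tricks.sliding_window_view(X, self.width, axis=1)
        z = np.einsum("bpw,fw->bpf", win, self.Wc) + self.bc
        a = np.maximum(z, 0.0)
        p = a.shape[1] - a.shape[1] % self.pool
        pooled_in = a[:, :p].reshape(X.shape[0], -1, self.pool, self.filters)
        pooled = pooled_in.max(axis=2)
        flat = pooled.reshape(X.shape[0], -1)
        if mask is not None:
            flat = flat * mask / (1.0 - self.dropout)
        score = flat @ self.Wd + self.bd
        prob = expit(score)
        cache = {
            "win": win, "z": z, "pooled_in": pooled_in, "pooled": pooled,
            "flat": flat, "prob": prob,
        }
        return prob, cache

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "CNNClassifier":
        X, y = _check_training_inputs(features, labels)
        n, d = X.shape
        if d < self.width:
            raise InvalidInputError(
                f"feature dimension {d} below convolution width {self.width}"
            )
        rng = np.random.default_rng(self.seed)
        n_pos = d - self.width + 1
        n_pool = n_pos // self.pool
        self.Wc = rng.normal(0.0, math.sqrt(2.0 / self.width), (self.filters, self.width))
        self.bc = np.zeros(self.filters)
        # small dense init keeps the untrained output near 0.5
        self.Wd = rng.normal(0.0, 0.01, n_pool * self.filters)
        self.bd = 0.0
        self.n_features_in_ = d

        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                mask = (
                    rng.random((idx.size, n_pool * self.filters)) >= self.dropout
                ).astype(float) if self.dropout else None
                prob, cache = self._forward(xb, mask)
                b = idx.size
                # dL/dscore for mean BCE
                dscore = (prob - yb) / b
                flat = cache["flat"]
                dWd = flat.T @ dscore
                dbd = dscore.sum()
                dflat = np.outer(dscore, self.Wd)
                if mask is not None:
                    dflat = dflat * mask / (1.0 - self.dropout)
                dpooled = dflat.reshape(b, n_pool, self.filters)
                pooled_in = cache["pooled_in"][:, :n_pool]
                winners = pooled_in == pooled_in.max(axis=2, keepdims=True)
                # distribute gradient to the (first) max within each pool window
                first = winners & (np.cumsum(winners, axis=2) == 1)
                da_pool = first * dpooled[:, :, None, :]
                da = np.zeros_like(cache["z"])
                da[:, : n_pool * self.pool] = da_pool.reshape(
                    b, n_pool * self.pool, self.filters
                )
                dz = da * (cache["z"] > 0)
                dWc = np.einsum("bpf,bpw->fw", dz, cache["win"])
                dbc = dz.sum(axis=(0, 1))
                lr = self.learning_rate
                self.Wd -= lr * dWd
                self.bd -= lr * dbd
                self.Wc -= lr * dWc
                self.bc -= lr * dbc
        return self

    def _check_fitted(self, X: np.ndarray) -> np.ndarray:
        if self.n_features_in_ is None:
            raise InvalidInputError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected features of dimension {self.n_features_in_}"
            )
        return X

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        """Sigmoid output probabilities; threshold at 0.5 gives hard labels."""
        prob, _ = self._forward(self._check_fitted(features))
        return prob

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.decision_scores(features) > 0.5).astype(int)


def train_cnn(
    features: np.ndarray,
    labels: np.ndarray,
    learning_rate: float = 5e-2,
    epochs: int = 150,
    batch_size: int = 16,
    seed: int = 0,
    **kwargs,
) -> CNNClassifier:
    model = CNNClassifier(
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
        **kwargs,
    )
    if epochs == 0:
        # expose the initialised network without a training pass
        X, y = _check_training_inputs(features, labels)
        rng = np.random.default_rng(seed)
        d = X.shape[1]
        n_pool = (d - model.width + 1) // model.pool
        model.Wc = rng.normal(0.0, math.sqrt(2.0 / model.width), (model.filters, model.width))
        model.bc = np.zeros(model.filters)
        model.Wd = rng.normal(0.0, 0.01, n_pool * model.filters)
        model.bd = 0.0
        model.n_features_in_ = d
        return model
    return model.fit(features, labels)


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def gain_ratio(
    labels: np.ndarray,
    feature_values: np.ndarray,
    split: float | None = None,
) -> float:
    """C4.5 information gain ratio of a split, in bits.

    With a numeric ``split`` threshold, samples partition into
    ``feature_values <= split`` versus the rest; with ``split=None`` the
    feature values themselves are treated as categorical group labels.
    Degenerate splits (any empty group, or fewer than 2 groups) return 0
    by convention.
    """
    y = np.asarray(labels)
    v = np.asarray(feature_values)
    if y.shape != v.shape:
        raise InvalidInputError("labels and feature_values must align")
    if y.size < 2:
        return 0.0
    groups = v <= split if split is not None else v
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        return 0.0
    h_total = _entropy_bits(y)
    weights = counts / y.size
    h_split = sum(
        w * _entropy_bits(y[groups == g]) for g, w in zip(uniq, weights)
    )
    gain = h_total - h_split
    iv = float(-(weights * np.log2(weights)).sum())
    if iv <= 0 or gain <= 0:
        return 0.0
    return float(gain / iv)


@dataclass
class _TreeNode:
    prediction: float  # positive fraction at the node
    n: int
    errors: int
    feature: int | None = None
    threshold: float | None = None
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class GainRatioTreeClassifier:
    """Binary decision tree with gain-ratio splits (C4.5 family).

    Splits are axis-aligned thresholds chosen to maximise the information
    gain ratio.  After growth the tree is pruned bottom-up by comparing
    pessimistic (upper-confidence-bound) error estimates at confidence
    ``prune_confidence``, a simplified form of C4.5's error-based pruning.
    """

    kind = "tree"

    def __init__(
        self,
        max_depth: int = 12,
        min_samples_leaf: int = 2,
        prune_confidence: float | None = 0.25,
        seed: int = 0,
    ):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.prune_confidence = prune_confidence
        self.seed = seed
        self.n_features_in_: int | None = None
        self._root: _TreeNode | None = None

    def _best_split(self, X: np.ndarray, y: np.ndarray) -> tuple[int, float, float]:
        best = (-1.0, -1, 0.0)  # (ratio, feature, threshold)
        for j in range(X.shape[1]):
            vals = np.unique(X[:, j])
            if vals.size < 2:
                continue
            mids = (vals[:-1] + vals[1:]) / 2.0
            for t in mids:
                left = X[:, j] <= t
                if (
                    left.sum() < self.min_samples_leaf
                    or (~left).sum() < self.min_samples_leaf
                ):
                    continue
                r = gain_ratio(y, X[:, j], split=float(t))
                if r > best[0]:
                    best = (r, j, float(t))
        return best[1], best[2], best[0]

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _TreeNode:
        frac = float(y.mean())
        errors = int(min(y.sum(), (1 - y).sum()))
        node = _TreeNode(prediction=frac, n=y.size, errors=errors)
        if depth >= self.max_depth or len(np.unique(y)) < 2:
            return node
        j, t, ratio = self._best_split(X, y)
        if j < 0 or ratio <= 0:
            return node
        mask = X[:, j] <= t
        node.feature, node.threshold = j, t
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def _pessimistic(self, errors: int, n: int) -> float:
        """Upper confidence bound on the error rate (normal approximation)."""
        z = float(norm.ppf(1.0 - self.prune_confidence))
        f = errors / n
        return f + z * math.sqrt(f * (1.0 - f) / n + 1e-12) + 0.5 / n

    def _prune(self, node: _TreeNode) -> float:
        """Return the pessimistic subtree error count, pruning in place."""
        if node.is_leaf:
            return self._pessimistic(node.errors, node.n) * node.n
        subtree = self._prune(node.left) + self._prune(node.right)
        as_leaf = self._pessimistic(node.errors, node.n) * node.n
        if as_leaf <= subtree:
            node.feature = node.threshold = node.left = node.right = None
            return as_leaf
        return subtree

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "GainRatioTreeClassifier":
        X, y = _check_training_inputs(features, labels)
        self._root = self._grow(X, y, depth=0)
        if self.prune_confidence is not None and not self._root.is_leaf:
            self._prune(self._root)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        """Leaf positive fractions; threshold at 0.5 gives hard labels."""
        if self._root is None:
            raise InvalidInputError("model is not fitted")
        X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected features of dimension {self.n_features_in_}"
            )
        out = np.empty(X.shape[0])
        for i, x in enumerate(X):
            node = self._root
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.decision_scores(features) > 0.5).astype(int)


def predict(model, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and continuous scores for any trained model."""
    scores = model.decision_scores(np.asarray(features, dtype=float))
    labels = model.predict(features)
    return labels, scores
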