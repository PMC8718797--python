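"""Gradient-boosted trees with a leaf-one-hot logistic-regression head.

The cascade has three stages:

1. **Boosting** on the binomial log-loss ``log(1 + exp(-y * score))`` with
   labels mapped to {-1, +1}.  The initial score is half the log ratio of
   positive to negative counts; each round fits a CART regression tree to
   the negative gradient (the residuals ``y / (1 + exp(y * score))``) and
   assigns each leaf the single-Newton-step value
   ``sum(r) / sum(|r| * (2 - |r|))``, applied with shrinkage ``alpha``.
2. **Leaf encoding**: each sample is mapped to the concatenated one-hot of
   the leaf it reaches in every tree (exactly T ones), turning the ensemble
   into a learned feature crossing.
3. **Logistic regression** on the leaf codes, trained by full-batch gradient
   descent on the cross-entropy (plus a small L2 term that keeps separable
   codes bounded).

All stages are deterministic: tree splits maximise squared-error reduction
with ties broken by lowest feature index, then lowest threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "RegressionTree",
    "BoostedEnsemble",
    "LogisticHead",
    "GBDTLRClassifier",
    "init_score",
    "residuals",
    "logloss",
    "fit_tree",
    "leaf_values",
    "boost",
    "encode_leaves",
    "lr_fit",
    "predict_pair",
]


def init_score(labels) -> float:
    """Initial boosting score: half the log-odds of the {0,1} labels."""
    y = np.asarray(labels)
    pos, neg = float((y == 1).sum()), float((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("initial score requires both classes present")
    return 0.5 * float(np.log(pos / neg))


def residuals(y_pm: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Negative log-loss gradient r = y / (1 + exp(y * score)), y in {-1,+1}."""
    y_pm = np.asarray(y_pm, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if y_pm.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    # exp overflow to inf is the correct limit: the residual becomes exactly 0
    with np.errstate(over="ignore"):
        return y_pm / (1.0 + np.exp(y_pm * scores))


def logloss(y_pm: np.ndarray, scores: np.ndarray) -> float:
    """Mean binomial deviance log(1 + exp(-y * score)) with y in {-1,+1}."""
    return float(np.logaddexp(0.0, -np.asarray(y_pm) * np.asarray(scores)).mean())


@dataclass
class RegressionTree:
    """Binary CART tree stored as parallel arrays.

    Internal node i: ``feature[i]``, ``threshold[i]`` (go left when
    ``x[feature] <= threshold``), children ``left[i]``/``right[i]``.
    Leaves have ``feature == -1`` and a slot in ``leaf_of_node``; leaf slots
    are numbered in depth-first, left-first construction order.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_of_node: np.ndarray
    values: np.ndarray = field(default=None)

    @property
    def n_leaves(self) -> int:
        return int((self.feature == -1).sum())

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf slot reached by every row of X (vectorised frontier descent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0], dtype=np.int64)
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if self.feature[node] == -1:
                out[idx] = self.leaf_of_node[node]
                continue
            mask = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((self.left[node], idx[mask]))
            stack.append((self.right[node], idx[~mask]))
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_of_node": self.leaf_of_node.tolist(),
            "values": None if self.values is None else self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            np.asarray(d["feature"], dtype=np.int64),
            np.asarray(d["threshold"], dtype=float),
            np.asarray(d["left"], dtype=np.int64),
            np.asarray(d["right"], dtype=np.int64),
            np.asarray(d["leaf_of_node"], dtype=np.int64),
            None if d["values"] is None else np.asarray(d["values"], dtype=float),
        )


def _best_split(X: np.ndarray, r: np.ndarray, min_leaf: int):
    """Exhaustive variance-reduction split search, deterministic tie-breaks.

    Returns (feature, threshold) or None.  Ties in gain resolve to the
    lowest feature index, then the lowest threshold.
    """
    n, f = X.shape
    if n < 2 * min_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    v = np.take_along_axis(X, order, axis=0)
    rs = r[order]
    csum = np.cumsum(rs, axis=0)
    total = csum[-1, :]
    n_left = np.arange(1, n)[:, None].astype(float)
    n_right = n - n_left
    gain = (csum[:-1] ** 2) / n_left + (total - csum[:-1]) ** 2 / n_right \
        - (total ** 2) / n
    valid = (v[:-1] < v[1:]) & (n_left >= min_leaf) & (n_right >= min_leaf)
    gain = np.where(valid, gain, -np.inf)
    best = gain.max()
    if not np.isfinite(best) or best <= 1e-12:
        return None
    # candidates ordered by (feature, split position) => lowest threshold first
    cand = np.argwhere(gain.T == best)
    fi, pos = int(cand[0, 0]), int(cand[0, 1])
    thr = 0.5 * (v[pos, fi] + v[pos + 1, fi])
    return fi, float(thr)


def fit_tree(X: np.ndarray, r: np.ndarray, max_depth: int = 3,
             min_leaf: int = 5) -> RegressionTree:
    """Greedy CART on residuals (structure only; values assigned later)."""
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    if X.ndim != 2 or X.shape[0] != r.shape[0]:
        raise ValueError("X and r must have matching first dimensions")
    feature, threshold, left, right, leaf_of_node = [], [], [], [], []
    leaf_count = 0

    def grow(idx: np.ndarray, depth: int) -> int:
        nonlocal leaf_count
        node = len(feature)
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf_of_node.append(-1)
        split = None
        if depth < max_depth and idx.size >= 2 * min_leaf and np.ptp(r[idx]) > 0:
            split = _best_split(X[idx], r[idx], min_leaf)
        if split is None:
            leaf_of_node[node] = leaf_count
            leaf_count += 1
            return node
        fi, thr = split
        feature[node] = fi
        threshold[node] = thr
        mask = X[idx, fi] <= thr
        left[node] = grow(idx[mask], depth + 1)
        right[node] = grow(idx[~mask], depth + 1)
        return node

    grow(np.arange(X.shape[0]), 0)
    return RegressionTree(
        np.asarray(feature, dtype=np.int64),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
        np.asarray(leaf_of_node, dtype=np.int64),
    )


def leaf_values(leaf_assign: np.ndarray, n_leaves: int, y_pm: np.ndarray,
                scores: np.ndarray) -> np.ndarray:
    """Single-Newton-step leaf value sum(r) / sum(|r| * (2 - |r|)) per leaf."""
    r = residuals(y_pm, scores)
    num = np.bincount(leaf_assign, weights=r, minlength=n_leaves)
    den = np.bincount(leaf_assign, weights=np.abs(r) * (2.0 - np.abs(r)),
                      minlength=n_leaves)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return c


@dataclass
class BoostedEnsemble:
    """Initial score, shrinkage and the fitted tree sequence."""

    init: float
    learning_rate: float
    trees: list
    train_losses: list = field(default_factory=list)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.full(X.shape[0], self.init)
        for tree in self.trees:
            scores += self.learning_rate * tree.values[tree.apply(X)]
        return scores

    @property
    def n_code_bits(self) -> int:
        return int(sum(t.n_leaves for t in self.trees))

    def to_dict(self) -> dict:
        return {"init": self.init, "learning_rate": self.learning_rate,
                "trees": [t.to_dict() for t in self.trees],
                "train_losses": list(self.train_losses)}

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedEnsemble":
        return cls(d["init"], d["learning_rate"],
                   [RegressionTree.from_dict(t) for t in d["trees"]],
                   list(d.get("train_losses", [])))


def boost(X: np.ndarray, labels, n_estimators: int = 100,
          learning_rate: float = 0.1, max_depth: int = 3,
          min_leaf: int = 5) -> BoostedEnsemble:
    """Fit the boosted ensemble on {0,1} labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if n_estimators < 1:
        raise ValueError("need at least one boosting round")
    theta0 = init_score(y)  # validates both classes present
    y_pm = np.where(y == 1, 1.0, -1.0)
    scores = np.full(X.shape[0], theta0)
    trees: list[RegressionTree] = []
    losses = [logloss(y_pm, scores)]
    for _ in range(n_estimators):
        r = residuals(y_pm, scores)
        tree = fit_tree(X, r, max_depth=max_depth, min_leaf=min_leaf)
        assign = tree.apply(X)
        tree.values = leaf_values(assign, tree.n_leaves, y_pm, scores)
        scores = scores + learning_rate * tree.values[assign]
        trees.append(tree)
        losses.append(logloss(y_pm, scores))
    return BoostedEnsemble(theta0, learning_rate, trees, losses)


def encode_leaves(ensemble: BoostedEnsemble, X: np.ndarray) -> np.ndarray:
    """Concatenated per-tree one-hot of reached leaves (exactly T ones per row)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    codes = np.zeros((n, ensemble.n_code_bits), dtype=np.float64)
    offset = 0
    for tree in ensemble.trees:
        codes[np.arange(n), offset + tree.apply(X)] = 1.0
        offset += tree.n_leaves
    return codes


@dataclass
class LogisticHead:
    """Logistic-regression weights over leaf codes; intercept is the last entry."""

    theta: np.ndarray
    l2: float
    n_steps: int
    grad_norm: float
    initial_loss: float
    final_loss: float

    def predict_proba(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=float))
        z = codes @ self.theta[:-1] + self.theta[-1]
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {"theta": self.theta.tolist(), "l2": self.l2,
                "n_steps": self.n_steps, "grad_norm": self.grad_norm,
                "initial_loss": self.initial_loss, "final_loss": self.final_loss}

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticHead":
        return cls(np.asarray(d["theta"], dtype=float), d["l2"], d["n_steps"],
                   d["grad_norm"], d["initial_loss"], d["final_loss"])


def _xent(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-15
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def lr_fit(codes: np.ndarray, labels, l2: float = 1e-4,
           max_steps: int = 3000, tol: float = 1e-6) -> LogisticHead:
    """Full-batch gradient descent on the cross-entropy over leaf codes.

    The step size is 1 over an upper bound of the gradient's Lipschitz
    constant (spectral norm of the design matrix by power iteration), so the
    loss decreases monotonically; iteration stops when the gradient norm
    drops below ``tol`` or at ``max_steps``.
    """
    X = np.atleast_2d(np.asarray(codes, dtype=float))
    y = np.asarray(labels, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("labels must be binary {0, 1}")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    m, dim = X.shape
    Xb = np.hstack([X, np.ones((m, 1))])
    # spectral norm by power iteration for a tight Lipschitz bound
    v = np.ones(dim + 1) / np.sqrt(dim + 1)
    for _ in range(30):
        w = Xb.T @ (Xb @ v)
        nv = np.linalg.norm(w)
        if nv == 0:
            break
        v = w / nv
    sigma2 = float(v @ (Xb.T @ (Xb @ v)))
    lipschitz = sigma2 / (4.0 * m) + l2
    step = 1.0 / lipschitz
    theta = np.zeros(dim + 1)
    reg_mask = np.ones(dim + 1)
    reg_mask[-1] = 0.0  # intercept unregularised
    p = 1.0 / (1.0 + np.exp(-(Xb @ theta)))
    initial_loss = _xent(p, y)
    grad_norm = np.inf
    steps = 0
    for steps in range(1, max_steps + 1):
        grad = Xb.T @ (p - y) / m + l2 * reg_mask * theta
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol:
            break
        theta -= step * grad
        p = 1.0 / (1.0 + np.exp(-(Xb @ theta)))
    final_loss = _xent(p, y)
    if final_loss > initial_loss + 1e-12:
        warnings.warn("logistic head training did not decrease the loss",
                      stacklevel=2)
    return LogisticHead(theta, l2, steps, grad_norm, initial_loss, final_loss)


def predict_pair(ensemble: BoostedEnsemble, head: LogisticHead,
                 x: np.ndarray) -> float:
    """Probability that a single feature vector is a positive pair."""
    codes = encode_leaves(ensemble, np.atleast_2d(x))
    return float(head.predict_proba(codes)[0])


class GBDTLRClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator for the boosted-tree / leaf-code / LR cascade.

    Parameters
    ----------
    n_estimators, learning_rate, max_depth, min_leaf:
        Boosting stage controls (rounds T, shrinkage alpha, CART depth cap,
        minimum samples per leaf).
    l2, lr_max_steps, lr_tol:
        Logistic head controls.

    Attributes (after fit)
    ----------------------
    ensemble_ : BoostedEnsemble
    head_ : LogisticHead
    classes_ : ndarray of the two class labels
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 3, min_leaf: int = 5, l2: float = 1e-4,
                 lr_max_steps: int = 3000, lr_tol: float = 1e-6):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.l2 = l2
        self.lr_max_steps = lr_max_steps
        self.lr_tol = lr_tol

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("GBDTLRClassifier is a binary classifier")
        y01 = (y == self.classes_[1]).astype(int)
        self.ensemble_ = boost(X, y01, n_estimators=self.n_estimators,
                               learning_rate=self.learning_rate,
                               max_depth=self.max_depth, min_leaf=self.min_leaf)
        codes = encode_leaves(self.ensemble_, X)
        self.head_ = lr_fit(codes, y01, l2=self.l2, max_steps=self.lr_max_steps,
                            tol=self.lr_tol)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "ensemble_")
        X = check_array(X)
        p1 = self.head_.predict_proba(encode_leaves(self.ensemble_, X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]

    def decision_function(self, X):
        check_is_fitted(self, "ensemble_")
        X = check_array(X)
        codes = encode_leaves(self.ensemble_, X)
        return codes @ self.head_.theta[:-1] + self.head_.theta[-1]

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "ensemble_")
        return json.dumps({
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "n_features_in": int(self.n_features_in_),
            "ensemble": self.ensemble_.to_dict(),
            "head": self.head_.to_dict(),
        })

    @classmethod
    def from_json(cls, text: str) -> "GBDTLRClassifier":
        d = json.loads(text)
        clf = cls(**d["params"])
        clf.classes_ = np.asarray(d["classes"])
        clf.n_features_in_ = d["n_features_in"]
        clf.ensemble_ = BoostedEnsemble.from_dict(d["ensemble"])
        clf.head_ = LogisticHead.from_dict(d["head"])
        return clf
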