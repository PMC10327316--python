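"""Deterministic CART regression tree (SSE criterion).

Greedy binary splitting minimizing within-node sum of squared errors.  A
split is kept only if it reduces total SSE by at least ``cp`` times the
root SSE and respects the min-split / min-leaf / max-depth controls.
Candidate thresholds are midpoints between consecutive distinct sorted
covariate values; rows with covariate value < threshold go left.  Ties in
SSE reduction are broken toward the lowest feature index, then the lowest
threshold, so fitting is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TreeControls", "Node", "RegressionTree", "fit_regression_tree"]


@dataclass(frozen=True)
class TreeControls:
    """Stopping/pruning controls for the tree and the EM loop around it.

    Defaults follow the conventions of the classical recursive-partitioning
    implementations: a node is considered for splitting only with at least
    ``min_split`` rows, children must keep ``min_leaf`` rows, and a split
    must improve total SSE by at least ``cp`` x root SSE.
    """
    min_split: int = 20
    min_leaf: int = 7
    cp: float = 0.01
    max_depth: int | None = None
    tol: float = 1e-3       # EM convergence tolerance on the log-likelihood
    max_iter: int = 100     # EM iteration cap

    def __post_init__(self):
        if not 0.0 <= self.cp <= 1.0:
            raise ValueError("cp must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.min_leaf < 1 or self.min_split < 2:
            raise ValueError("min_leaf >= 1 and min_split >= 2 required")


@dataclass
class Node:
    n: int
    value: float                 # mean response of routed training rows
    sse: float
    feature: int | None = None   # None for a terminal node
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    leaf_id: int = -1            # filled after growth, depth-first order

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self, feature_names=None) -> dict:
        if self.is_leaf:
            return {"leaf_id": self.leaf_id, "n": self.n, "value": self.value}
        name = (feature_names[self.feature]
                if feature_names is not None else self.feature)
        return {"feature": name, "threshold": self.threshold, "n": self.n,
                "left": self.left.to_dict(feature_names),
                "right": self.right.to_dict(feature_names)}


def _node_stats(y: np.ndarray) -> tuple[float, float]:
    mu = float(y.mean())
    return mu, float(((y - mu) ** 2).sum())


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive best split over all features and midpoint thresholds.

    Returns (reduction, feature, threshold) or None.  First-encountered
    maximum wins under ascending feature/threshold order.
    """
    n, p = X.shape
    _, parent_sse = _node_stats(y)
    best = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        ys = y[order]
        cum1 = np.cumsum(ys)
        cum2 = np.cumsum(ys ** 2)
        tot1, tot2 = cum1[-1], cum2[-1]
        # split after position m-1 (m rows left); valid where value changes
        m = np.arange(1, n)
        valid = xs[1:] != xs[:-1]
        valid &= (m >= min_leaf) & (n - m >= min_leaf)
        if not valid.any():
            continue
        mv = m[valid]
        left_sse = cum2[mv - 1] - cum1[mv - 1] ** 2 / mv
        r1 = tot1 - cum1[mv - 1]
        r2 = tot2 - cum2[mv - 1]
        right_sse = r2 - r1 ** 2 / (n - mv)
        red = parent_sse - (left_sse + right_sse)
        k = int(np.argmax(red))  # first max -> lowest threshold
        if best is None or red[k] > best[0]:
            thr = 0.5 * (xs[mv[k] - 1] + xs[mv[k]])
            best = (float(red[k]), j, float(thr))
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, root_sse: float,
          controls: TreeControls) -> Node:
    mu, sse = _node_stats(y)
    node = Node(n=len(y), value=mu, sse=sse)
    if len(y) < controls.min_split:
        return node
    if controls.max_depth is not None and depth >= controls.max_depth:
        return node
    best = _best_split(X, y, controls.min_leaf)
    if best is None or best[0] <= 0 or best[0] < controls.cp * root_sse:
        return node
    _, j, thr = best
    mask = X[:, j] < thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], depth + 1, root_sse, controls)
    node.right = _grow(X[~mask], y[~mask], depth + 1, root_sse, controls)
    return node


@dataclass
class RegressionTree:
    root: Node
    n_features: int
    controls: TreeControls
    feature_names: list[str] | None = None
    leaves: list[Node] = field(default_factory=list)

    def __post_init__(self):
        if not self.leaves:
            self._index_leaves()

    def _index_leaves(self):
        self.leaves = []

        def walk(node: Node):
            if node.is_leaf:
                node.leaf_id = len(self.leaves)
                self.leaves.append(node)
            else:
                walk(node.left)
                walk(node.right)
        walk(self.root)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for each row of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} feature columns")
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] < node.threshold else node.right
            out[i] = node.leaf_id
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        values = np.array([leaf.value for leaf in self.leaves])
        return values[self.apply(X)]

    def set_leaf_values(self, values) -> None:
        """Replace terminal-node predictions (one value per leaf)."""
        values = np.asarray(values, dtype=float)
        if values.size != self.n_leaves:
            raise ValueError("one value per terminal node required")
        for leaf, v in zip(self.leaves, values):
            leaf.value = float(v)

    def to_dict(self) -> dict:
        return {"n_features": self.n_features,
                "feature_names": self.feature_names,
                "controls": {"min_split": self.controls.min_split,
                             "min_leaf": self.controls.min_leaf,
                             "cp": self.controls.cp,
                             "max_depth": self.controls.max_depth},
                "tree": self.root.to_dict(self.feature_names)}


def fit_regression_tree(X, y, controls: TreeControls | None = None,
                        feature_names: list[str] | None = None) -> RegressionTree:
    """Fit a deterministic SSE-minimizing regression tree."""
    if controls is None:
        controls = TreeControls()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or len(y) == 0:
        raise ValueError("features and response must be aligned and non-empty")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in tree inputs; impute first")
    _, root_sse = _node_stats(y)
    root = _grow(X, y, 0, root_sse, controls)
    return RegressionTree(root=root, n_features=X.shape[1],
                          controls=controls, feature_names=feature_names)
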