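"""Binary classification trees (CART) with exhaustive Gini cut search.

Small recursive partitioner in the rpart mould: at each node every numeric
predictor is scanned over all split midpoints, the split with the largest
Gini impurity decrease wins, and a split is kept only when its root-scaled
improvement exceeds the complexity penalty.  Node counts, the first split,
and a text rendering are exposed for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CARTConfig:
    min_split: int = 20        # smallest node that may be split
    min_leaf: int = 7          # smallest allowed child
    #: complexity penalty on the misclassification-risk scale, relative to
    #: the root risk: a subtree survives pruning only if it removes at
    #: least cp * root-risk misclassifications per added leaf
    cp: float = 0.01
    max_depth: int = 10


@dataclass
class CARTNode:
    n: int
    counts: tuple[int, int]            # (non-events, events)
    gini: float
    predicted: int
    split_var: str | None = None
    split_value: float | None = None   # left branch: x <= value
    left: "CARTNode | None" = None
    right: "CARTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "counts": list(self.counts), "gini": self.gini,
             "predicted": self.predicted}
        if not self.is_leaf:
            d.update(split_var=self.split_var, split_value=self.split_value,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class CARTTree:
    root: CARTNode
    features: list[str]
    config: CARTConfig

    @property
    def first_split(self) -> tuple[str, float] | None:
        if self.root.is_leaf:
            return None
        return self.root.split_var, self.root.split_value

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(X), dtype=int)
        for i, (_, row) in enumerate(X.iterrows()):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.split_var] <= node.split_value \
                    else node.right
            out[i] = node.predicted
        return out

    def render(self) -> str:
        lines: list[str] = []

        def walk(node: CARTNode, prefix: str, label: str) -> None:
            tag = (f"{label} n={node.n} counts={node.counts} "
                   f"class={node.predicted}")
            lines.append(prefix + tag)
            if not node.is_leaf:
                walk(node.left, prefix + "  ",
                     f"{node.split_var} <= {node.split_value:.4g}:")
                walk(node.right, prefix + "  ",
                     f"{node.split_var} > {node.split_value:.4g}:")

        walk(self.root, "", "root")
        return "\n".join(lines)


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def best_split_brute_force(x: np.ndarray, y: np.ndarray,
                           min_leaf: int = 1) -> tuple[float, float] | None:
    """Gini-optimal cut over all midpoints of distinct sorted values.

    Returns ``(cut, impurity_decrease)`` or None.  Quadratic and simple;
    serves both as the per-feature search and as an independent check.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    parent = _gini(np.bincount(ys, minlength=2))
    n = len(ys)
    best = None
    for i in range(min_leaf - 1, n - min_leaf):
        if xs[i] == xs[i + 1]:
            continue
        left = np.bincount(ys[:i + 1], minlength=2)
        right = np.bincount(ys[i + 1:], minlength=2)
        child = ((i + 1) * _gini(left) + (n - i - 1) * _gini(right)) / n
        dec = parent - child
        if best is None or dec > best[1]:
            best = ((xs[i] + xs[i + 1]) / 2.0, dec)
    return best


def fit_cart(table: pd.DataFrame, outcome: str, features: list[str],
             config: CARTConfig | None = None) -> CARTTree:
    """Recursive binary partitioning of a 0/1 outcome.

    Splitting maximises the Gini impurity decrease; the grown tree is then
    pruned bottom-up on the misclassification-risk scale: an internal node
    is collapsed unless its subtree removes at least
    ``cp * root-risk`` misclassifications per added leaf (weakest-link
    pruning with a fixed complexity parameter, as in recursive
    partitioning practice).  A pure or small node becomes a leaf.
    """
    config = config or CARTConfig()
    df = table[[outcome, *features]].dropna()
    y_all = df[outcome].astype(int).to_numpy()
    if not np.isin(y_all, [0, 1]).all():
        raise ValueError("CART outcome must be binary 0/1")
    X_all = df[features].astype(float).to_numpy()
    n_root = len(y_all)

    def grow(idx: np.ndarray, depth: int) -> CARTNode:
        y = y_all[idx]
        counts = np.bincount(y, minlength=2)
        node = CARTNode(n=len(y), counts=(int(counts[0]), int(counts[1])),
                        gini=_gini(counts), predicted=int(counts.argmax()))
        if (len(y) < config.min_split or node.gini == 0.0
                or depth >= config.max_depth):
            return node
        best = None
        for j, feat in enumerate(features):
            cand = best_split_brute_force(X_all[idx, j], y, config.min_leaf)
            if cand is not None and (best is None or cand[1] > best[2]):
                best = (feat, cand[0], cand[1], j)
        if best is None or best[2] <= 1e-12:
            return node
        feat, cut, dec, j = best
        go_left = X_all[idx, j] <= cut
        node.split_var, node.split_value = feat, float(cut)
        node.left = grow(idx[go_left], depth + 1)
        node.right = grow(idx[~go_left], depth + 1)
        return node

    root = grow(np.arange(n_root), 0)
    if n_root:
        root_risk = min(root.counts) / n_root
        if root_risk > 0:
            _prune(root, n_root, root_risk, config.cp)
    return CARTTree(root=root, features=list(features), config=config)


def _subtree_risk_leaves(node: CARTNode, n_root: int) -> tuple[float, int]:
    if node.is_leaf:
        return min(node.counts) / n_root, 1
    rl, ll = _subtree_risk_leaves(node.left, n_root)
    rr, lr = _subtree_risk_leaves(node.right, n_root)
    return rl + rr, ll + lr


def _prune(node: CARTNode, n_root: int, root_risk: float, cp: float) -> None:
    if node.is_leaf:
        return
    _prune(node.left, n_root, root_risk, cp)
    _prune(node.right, n_root, root_risk, cp)
    risk_here = min(node.counts) / n_root
    risk_sub, leaves = _subtree_risk_leaves(node, n_root)
    if risk_here - risk_sub < cp * root_risk * (leaves - 1):
        node.split_var = node.split_value = None
        node.left = node.right = None
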