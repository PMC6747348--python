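"""Monte Carlo Feature Selection: relative-importance (RI) ranking.

Features are ranked by aggregating, over p bootstrap sets × t random
feature projections (one entropy decision tree per combination), each
feature's split contributions:

    RI_g = Σ_τ (wAcc_τ)^u · Σ_{nodes of τ splitting on g}
           IG(node) · (n_node / n_root)^v

where wAcc_τ is the macro-averaged per-class recall of tree τ on its
held-out samples (out-of-bag by default), IG is the entropy information
gain of the split (bits), and u = v = 1 by default.  Features never chosen
as a split anywhere have RI exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import BetaMatrix

__all__ = [
    "McfsConfig",
    "TreeNode",
    "DecisionTree",
    "RIScoreTable",
    "MCFSRanker",
    "draw_projection",
    "bootstrap_split",
    "grow_tree",
    "weighted_accuracy",
    "macro_recall",
    "accumulate_ri",
    "ri_scores",
]


@dataclass
class McfsConfig:
    """Knobs of the Monte Carlo run.

    p bootstrap sets × t projections of m features each (m defaults to
    ⌈0.05·M⌉).  ``holdout`` selects the per-tree evaluation set: "oob"
    (out-of-bag samples of the bootstrap, the default) or "split" (the
    bootstrap itself split 2:1 into train/eval).
    """

    p: int = 20
    t: int = 50
    m: int | None = None
    u: float = 1.0
    v: float = 1.0
    min_leaf: int = 2
    holdout: str = "oob"
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.p < 1 or self.t < 1:
            raise ValueError("p and t must be ≥ 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be ≥ 1")
        if self.holdout not in ("oob", "split"):
            raise ValueError("holdout must be 'oob' or 'split'")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be ≥ 1")
        if n_features is not None and self.m is not None and self.m > n_features:
            raise ValueError(f"m ({self.m}) exceeds feature count ({n_features})")

    def resolve_m(self, n_features: int) -> int:
        if self.m is not None:
            return self.m
        return max(1, math.ceil(0.05 * n_features))


@dataclass
class TreeNode:
    """One node of a scoring tree.

    Split nodes carry the split feature (local projection index), threshold,
    information gain in bits and sample count; leaves have no split.
    """

    split_feature: int | None
    split_threshold: float | None
    information_gain: float
    node_sample_count: int
    class_counts: np.ndarray
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


@dataclass
class DecisionTree:
    """A grown scoring tree plus its held-out weighted accuracy.

    ``feature_indices`` maps the tree's local feature indices back to global
    column indices of the full matrix (identity when None).
    """

    root: TreeNode
    root_sample_count: int
    classes: np.ndarray
    wacc: float | None = None
    feature_indices: np.ndarray | None = None
    _clf: DecisionTreeClassifier | None = field(default=None, repr=False)

    def predict(self, X) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("tree was not grown from data; cannot predict")
        return self._clf.predict(X)

    def split_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out


def draw_projection(M: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform feature subset of size m without replacement (sorted)."""
    if m > M:
        raise ValueError(f"m ({m}) exceeds M ({M})")
    return np.sort(rng.choice(M, size=m, replace=False))


def bootstrap_split(
    n_samples: int, rng: np.random.Generator, max_retries: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap draw of size n plus its out-of-bag complement.

    Redraws (bounded) if the bag happens to contain every sample, so the
    held-out set is never empty.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    for _ in range(max_retries):
        train = rng.integers(0, n_samples, size=n_samples)
        held_out = np.setdiff1d(np.arange(n_samples), train)
        if held_out.size:
            return train, held_out
    raise RuntimeError("could not draw a bootstrap with non-empty out-of-bag set")


def _build_nodes(tree, node_id: int) -> TreeNode:
    left = tree.children_left[node_id]
    right = tree.children_right[node_id]
    # tree_.value holds per-class fractions; rescale to counts
    counts = tree.value[node_id][0] * tree.weighted_n_node_samples[node_id]
    counts = np.rint(counts).astype(int)
    n_node = int(tree.n_node_samples[node_id])
    if left == -1:  # leaf
        return TreeNode(None, None, 0.0, n_node, counts)
    nl = tree.n_node_samples[left]
    nr = tree.n_node_samples[right]
    ig = tree.impurity[node_id] - (
        nl * tree.impurity[left] + nr * tree.impurity[right]
    ) / (nl + nr)
    return TreeNode(
        int(tree.feature[node_id]),
        float(tree.threshold[node_id]),
        float(max(ig, 0.0)),
        n_node,
        counts,
        (_build_nodes(tree, left), _build_nodes(tree, right)),
    )


def grow_tree(
    X, y, min_leaf: int = 2, random_state: int | None = None
) -> DecisionTree:
    """Grow one entropy CART tree and expose per-node gain/count structure.

    Binary numeric splits maximize information gain; growth stops on pure
    nodes, the min_leaf floor, or absence of a positive-gain split, so a
    single-class training set yields a stump that contributes nothing to any
    feature's RI.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    clf = DecisionTreeClassifier(
        criterion="entropy",
        min_samples_leaf=min_leaf,
        min_impurity_decrease=1e-12,
        random_state=random_state,
    )
    clf.fit(X, y)
    root = _build_nodes(clf.tree_, 0)
    return DecisionTree(root, int(X.shape[0]), clf.classes_, _clf=clf)


def macro_recall(y_true, y_pred) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(recalls))


def weighted_accuracy(tree: DecisionTree, X_held, y_held) -> float:
    """Macro-averaged per-class recall of the tree on held-out samples."""
    y_held = np.asarray(y_held)
    if y_held.size == 0:
        raise ValueError("held-out set is empty")
    return macro_recall(y_held, tree.predict(np.asarray(X_held, dtype=float)))


def accumulate_ri(
    tree: DecisionTree, ri: np.ndarray, u: float = 1.0, v: float = 1.0
) -> None:
    """Add one tree's split contributions into the RI accumulator (in place).

    Each node splitting on feature g adds
    (wAcc)^u · IG(node) · (n_node / n_root)^v to ri[g] (g in global indices
    via ``tree.feature_indices``).
    """
    if tree.wacc is None:
        raise ValueError("tree has no wAcc; evaluate it on held-out samples first")
    wacc_term = tree.wacc**u
    root_n = tree.root_sample_count
    for node in tree.split_nodes():
        g = node.split_feature
        if tree.feature_indices is not None:
            g = int(tree.feature_indices[g])
        ri[g] += (
            wacc_term
            * node.information_gain
            * (node.node_sample_count / root_n) ** v
        )


@dataclass
class RIScoreTable:
    """Per-probe RI scores and the derived descending-order feature list."""

    scores: pd.Series

    @property
    def ranked(self) -> list[str]:
        order = sorted(self.scores.index, key=lambda p: (-self.scores[p], p))
        return order


class MCFSRanker(BaseEstimator):
    """Monte Carlo Feature Selection ranker (scikit-learn style).

    Fitting grows ``p × t`` entropy trees on bootstrap × projection
    combinations and accumulates each feature's relative importance.

    Attributes
    ----------
    ri_scores_ : ndarray of shape (n_features,)
        Accumulated RI per feature (0 for features never split on).
    ranking_ : ndarray of shape (n_features,)
        Feature indices sorted by RI descending (ties → lower index).
    """

    def __init__(
        self,
        p: int = 20,
        t: int = 50,
        m: int | None = None,
        u: float = 1.0,
        v: float = 1.0,
        min_leaf: int = 2,
        holdout: str = "oob",
        seed: int = 0,
    ):
        self.p = p
        self.t = t
        self.m = m
        self.u = u
        self.v = v
        self.min_leaf = min_leaf
        self.holdout = holdout
        self.seed = seed

    def _config(self) -> McfsConfig:
        return McfsConfig(
            self.p, self.t, self.m, self.u, self.v, self.min_leaf, self.holdout, self.seed
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        cfg = self._config()
        cfg.validate(X.shape[1])
        M = X.shape[1]
        m = cfg.resolve_m(M)
        n = X.shape[0]
        rng = np.random.default_rng(cfg.seed)
        ri = np.zeros(M)
        for _ in range(cfg.p):
            if cfg.holdout == "oob":
                train_idx, held_idx = bootstrap_split(n, rng)
            else:
                bag = rng.integers(0, n, size=n)
                perm = rng.permutation(bag)
                cut = max(1, (2 * n) // 3)
                train_idx, held_idx = perm[:cut], perm[cut:]
                if held_idx.size == 0:
                    train_idx, held_idx = perm[:-1], perm[-1:]
            y_train, y_held = y[train_idx], y[held_idx]
            for _ in range(cfg.t):
                proj = draw_projection(M, m, rng)
                tree_seed = int(rng.integers(0, 2**31 - 1))
                tree = grow_tree(
                    X[np.ix_(train_idx, proj)],
                    y_train,
                    min_leaf=cfg.min_leaf,
                    random_state=tree_seed,
                )
                tree.feature_indices = proj
                tree.wacc = weighted_accuracy(tree, X[np.ix_(held_idx, proj)], y_held)
                accumulate_ri(tree, ri, cfg.u, cfg.v)
        self.ri_scores_ = ri
        self.ranking_ = np.lexsort((np.arange(M), -ri))
        self.n_features_in_ = M
        return self

    def top_k(self, k: int) -> np.ndarray:
        check_is_fitted(self, "ranking_")
        return self.ranking_[:k]


def ri_scores(matrix: BetaMatrix, config: McfsConfig | None = None) -> RIScoreTable:
    """Rank the probes of a labeled BetaMatrix by RI score."""
    config = config or McfsConfig()
    config.validate(matrix.n_probes)
    ranker = MCFSRanker(
        p=config.p,
        t=config.t,
        m=config.m,
        u=config.u,
        v=config.v,
        min_leaf=config.min_leaf,
        holdout=config.holdout,
        seed=config.seed,
    ).fit(matrix.values, matrix.labels.astype(str))
    return RIScoreTable(pd.Series(ranker.ri_scores_, index=matrix.probe_ids, name="ri"))
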