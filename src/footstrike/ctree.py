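"""Conditional-inference-style recursive partitioning.

At each node every candidate feature is tested for association with the
response using the permutation framework of linear statistics: for feature x
and response influence h(y) (the response itself for regression, one-hot
class indicators for classification), the statistic ``T = sum_i x_i h(y_i)``
has closed-form conditional mean and covariance under random permutations of
the response,

    E(T)   = (sum_i x_i) h_bar,
    Cov(T) = S_x Sigma_h / (n - 1),

with ``S_x`` the centered sum of squares of x and ``Sigma_h`` the centered
scatter matrix of h.  The quadratic form of the standardized statistic is
referred to a chi-square distribution and the resulting p-values are
Bonferroni-adjusted across the candidate features.  A node is split only if
the best adjusted p-value is at or below ``alpha`` (0.01 by default, i.e. a
minimum splitting criterion of 0.99); the cutpoint maximizes the analogous
two-sample statistic.  This is a faithful simplification of the published
conditional-inference framework, not a bit-exact clone of any reference
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError, InputError, NotFittedError
from .features import FEATURE_COLUMNS
from .models import ClassThresholds, DEFAULT_THRESHOLDS, classify_fsp
from .simulate import FSP_CLASSES

__all__ = ["TreeNode", "TreeModel", "fit_ctree"]

_MAX_CUTS = 64


@dataclass
class TreeNode:
    """One node of a fitted tree: either a split or a leaf."""

    n: int
    depth: int
    # split fields (internal nodes)
    feature: Optional[str] = None
    threshold: Optional[float] = None
    p_adjusted: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    # leaf payload
    value: Optional[float] = None                 # mean response (regression)
    class_proportions: Optional[np.ndarray] = None  # in FSP_CLASSES order

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "n": self.n,
                "depth": self.depth,
                "value": self.value,
                "class_proportions": None
                if self.class_proportions is None
                else list(map(float, self.class_proportions)),
            }
        return {
            "n": self.n,
            "depth": self.depth,
            "feature": self.feature,
            "threshold": self.threshold,
            "p_adjusted": self.p_adjusted,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "feature" not in d:
            props = d.get("class_proportions")
            return cls(
                n=d["n"],
                depth=d["depth"],
                value=d.get("value"),
                class_proportions=None if props is None else np.asarray(props),
            )
        return cls(
            n=d["n"],
            depth=d["depth"],
            feature=d["feature"],
            threshold=d["threshold"],
            p_adjusted=d["p_adjusted"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class TreeModel:
    """A fitted conditional-inference tree for FSA prediction or FSP classes."""

    root: TreeNode
    task: str
    features: tuple[str, ...]
    alpha: float
    max_depth: int
    classes: tuple[str, ...] = FSP_CLASSES

    @property
    def depth(self) -> int:
        def walk(node: TreeNode) -> int:
            if node.is_leaf:
                return node.depth
            return max(walk(node.left), walk(node.right))

        return walk(self.root)

    @property
    def first_split_feature(self) -> Optional[str]:
        return self.root.feature

    def _leaf_for(self, row: np.ndarray, idx: dict[str, int]) -> TreeNode:
        node = self.root
        while not node.is_leaf:
            node = node.left if row[idx[node.feature]] <= node.threshold else node.right
        return node

    def predict(self, table: pd.DataFrame):
        if self.root is None:
            raise NotFittedError("tree has no root")
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise InputError(f"missing features: {missing}")
        X = table[list(self.features)].to_numpy(dtype=float)
        idx = {f: i for i, f in enumerate(self.features)}
        if self.task == "classify":
            out = np.empty(len(X), dtype=object)
            for i, row in enumerate(X):
                props = self._leaf_for(row, idx).class_proportions
                out[i] = self.classes[int(np.argmax(props))]
            return out
        return np.array([self._leaf_for(row, idx).value for row in X])

    def predict_class(self, table, thr: ClassThresholds = DEFAULT_THRESHOLDS):
        if self.task == "classify":
            return self.predict(table)
        return classify_fsp(self.predict(table), thr)

    def to_dict(self) -> dict:
        return {
            "kind": "ctree",
            "task": self.task,
            "features": list(self.features),
            "alpha": self.alpha,
            "max_depth": self.max_depth,
            "classes": list(self.classes),
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            task=d["task"],
            features=tuple(d["features"]),
            alpha=d["alpha"],
            max_depth=d["max_depth"],
            classes=tuple(d["classes"]),
        )


def _influence(y: np.ndarray, task: str, classes: tuple[str, ...]) -> np.ndarray:
    if task == "predict":
        return np.asarray(y, dtype=float)[:, None]
    onehot = np.zeros((len(y), len(classes)))
    lut = {c: j for j, c in enumerate(classes)}
    for i, label in enumerate(y):
        try:
            onehot[i, lut[label]] = 1.0
        except KeyError:
            raise InputError(f"unknown class label {label!r}") from None
    return onehot


def _quad_stat(g: np.ndarray, hc: np.ndarray, sigma_pinv: np.ndarray, n: int) -> float:
    """Standardized quadratic form of the linear statistic T = sum g*h."""
    s_g = float(np.sum((g - g.mean()) ** 2))
    if s_g <= 0:
        return 0.0
    t_c = g @ hc  # equals T - E(T) because hc is centered
    return float((n - 1) / s_g * t_c @ sigma_pinv @ t_c)


def _best_cut(x: np.ndarray, hc: np.ndarray, sigma_pinv: np.ndarray, n: int,
              min_bucket: int) -> Optional[tuple[float, float]]:
    """Cutpoint maximizing the two-sample statistic; None if no admissible cut."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cumsum = np.cumsum(hc[order], axis=0)  # C_r = sum_{i<=r} centered h
    # admissible cut after position r (1-based count r+1 on the left)
    counts = np.arange(1, n)
    valid = (xs[:-1] < xs[1:]) & (counts >= min_bucket) & (n - counts >= min_bucket)
    if not np.any(valid):
        return None
    c_r = cumsum[:-1][valid]
    r = counts[valid].astype(float)
    s_g = r * (n - r) / n
    stat = (n - 1) / s_g * np.einsum("ij,jk,ik->i", c_r, sigma_pinv, c_r)
    k = int(np.argmax(stat))
    pos = np.flatnonzero(valid)[k]
    threshold = 0.5 * (xs[pos] + xs[pos + 1])
    return float(threshold), float(stat[k])


def fit_ctree(
    train: pd.DataFrame,
    task: str = "predict",
    response: str | None = None,
    features: tuple[str, ...] = FEATURE_COLUMNS,
    alpha: float = 0.01,
    max_depth: int | None = None,
    min_node: int = 20,
    min_bucket: int = 7,
) -> TreeModel:
    """Grow a conditional-inference tree on a feature table.

    ``max_depth`` defaults to 8 for FSA prediction and 6 for FSP
    classification.  Nodes smaller than ``min_node`` become leaves, as do
    nodes where no feature achieves a Bonferroni-adjusted p-value <= alpha.
    """
    if task not in ("predict", "classify"):
        raise ConfigError(f"unknown task {task!r}")
    if len(train) == 0:
        raise InputError("empty training table")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if max_depth is None:
        max_depth = 8 if task == "predict" else 6
    if response is None:
        response = "true_fsa_deg" if task == "predict" else "true_class"
    cols = [f for f in features if f in train.columns]
    if not cols:
        raise InputError("no candidate features present")

    X = train[cols].to_numpy(dtype=float)
    y = train[response].to_numpy()
    classes = FSP_CLASSES

    def make_leaf(idx: np.ndarray, depth: int) -> TreeNode:
        if task == "predict":
            return TreeNode(n=len(idx), depth=depth, value=float(np.mean(y[idx])))
        h = _influence(y[idx], task, classes)
        return TreeNode(n=len(idx), depth=depth,
                        class_proportions=h.mean(axis=0))

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        n = len(idx)
        if n < min_node or depth >= max_depth:
            return make_leaf(idx, depth)
        h = _influence(y[idx], task, classes)
        hc = h - h.mean(axis=0)
        # Cov(T) = S_g * scatter / (n-1); the (n-1)/S_g factor lives in the
        # statistic, so the pseudo-inverse is of the raw centered scatter
        scatter = hc.T @ hc
        rank = int(np.linalg.matrix_rank(scatter)) if scatter.size > 1 else int(
            scatter[0, 0] > 0
        )
        if rank == 0:
            return make_leaf(idx, depth)  # constant response
        sigma_pinv = np.linalg.pinv(scatter)

        best_p, best_j = np.inf, None
        m = 0
        for j, _ in enumerate(cols):
            g = X[idx, j]
            if np.ptp(g) == 0:
                continue
            m += 1
            stat = _quad_stat(g, hc, sigma_pinv, n)
            p = float(chi2.sf(stat, df=rank))
            if p < best_p:
                best_p, best_j = p, j
        if best_j is None:
            return make_leaf(idx, depth)
        p_adj = min(1.0, best_p * m)  # Bonferroni across tested candidates
        if p_adj > alpha:
            return make_leaf(idx, depth)

        cut = _best_cut(X[idx, best_j], hc, sigma_pinv, n, min_bucket)
        if cut is None:
            return make_leaf(idx, depth)
        threshold, _ = cut
        mask = X[idx, best_j] <= threshold
        node = TreeNode(
            n=n,
            depth=depth,
            feature=cols[best_j],
            threshold=threshold,
            p_adjusted=p_adj,
            left=grow(idx[mask], depth + 1),
            right=grow(idx[~mask], depth + 1),
        )
        return node

    root = grow(np.arange(len(train)), 0)
    return TreeModel(root=root, task=task, features=tuple(cols), alpha=alpha,
                     max_depth=max_depth)
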