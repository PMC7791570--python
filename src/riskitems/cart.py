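"""Classification-tree sensitivity analysis over pooled risk-scale items.

Greedy recursive binary partitioning with the Gini impurity criterion,
mirroring how CART is applied to risk stratification after self-harm: all
binary (or binarised) scale items are pooled, the split maximising the
weighted Gini decrease is chosen at each node, and no pruning, stopping
rules or misclassification costs are applied. With binary predictors each
split is simply "item = 0 vs item = 1".

Leaves are classified low/high risk by comparing the leaf's positive
fraction with the training prevalence (ties classify high — the
conservative direction for a screening context); plain majority voting is
available via ``CartParams(classify="majority")`` but at a 30% event rate it
labels every leaf low risk, which defeats risk stratification.

Rows missing the split variable are excluded at that split during fitting
(listwise per split); at prediction time such rows stop at the deepest node
they reach and take that node's class and positive fraction. Surrogate
splits are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accuracy import AccuracyResult, AUCResult, dual_statistics, roc_auc, two_by_two
from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "CartParams",
    "TreeNode",
    "gini_impurity",
    "best_split",
    "fit_tree",
    "predict_tree",
    "tree_accuracy",
    "tree_to_dict",
    "tree_from_dict",
    "render_tree",
]


@dataclass(frozen=True)
class CartParams:
    """Tree-growing controls. Defaults grow the tree to purity: no pruning,
    no stopping rules, no misclassification costs."""

    criterion: str = "gini"
    max_depth: int | None = None
    min_node_size: int = 1
    misclassification_costs: None = None  # costs are out of scope; must stay None
    classify: str = "prevalence"  # prevalence | majority

    def __post_init__(self) -> None:
        if self.criterion != "gini":
            raise ConfigurationError("only the Gini criterion is supported")
        if self.misclassification_costs is not None:
            raise ConfigurationError("misclassification costs are not supported")
        if self.min_node_size < 1:
            raise ConfigurationError("min_node_size must be >= 1")
        if self.classify not in ("prevalence", "majority"):
            raise ConfigurationError(f"unknown classify rule {self.classify!r}")


@dataclass
class TreeNode:
    """A node of the fitted tree; a leaf iff ``split_item`` is None.

    ``left`` holds episodes with the split item = 0, ``right`` = 1. Every
    node (internal or leaf) carries its own counts, positive fraction and
    risk class so that rows with missing split values can be scored at the
    deepest node they reach.
    """

    n: int
    n_positive: int
    depth: int
    prediction: str  # "low" | "high"
    split_item: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n

    @property
    def is_leaf(self) -> bool:
        return self.split_item is None


def gini_impurity(n_pos: int, n: int) -> float:
    """Gini impurity 1 - p^2 - (1-p)^2 of a binary node with n_pos of n positive."""
    if n <= 0:
        raise DegenerateInputError("Gini impurity needs n > 0")
    if not 0 <= n_pos <= n:
        raise ValueError(f"need 0 <= n_pos <= n, got {n_pos}/{n}")
    p = n_pos / n
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def best_split(
    items: pd.DataFrame, outcomes: pd.Series, candidate_items: Sequence[str]
) -> tuple[str, float] | None:
    """Item maximising the weighted Gini decrease, or None if nothing splits.

    For each candidate, rows missing that item are set aside and the
    decrease is measured on the remaining rows (impurity of the observed
    subset minus the size-weighted impurity of its two children). Candidates
    with no variation are unsplittable. Ties keep the earliest item in
    ``candidate_items`` order.
    """
    y = outcomes.to_numpy()
    best_item: str | None = None
    best_dec = 0.0
    for item in candidate_items:
        col = items[item]
        keep = col.notna().to_numpy()
        if not keep.any():
            continue
        x = col[keep].astype(int).to_numpy()
        yk = y[keep]
        n = len(yk)
        n1 = int(x.sum())
        n0 = n - n1
        if n0 == 0 or n1 == 0:
            continue
        parent = gini_impurity(int(yk.sum()), n)
        pos1 = int(yk[x == 1].sum())
        pos0 = int(yk.sum()) - pos1
        child = (n0 * gini_impurity(pos0, n0) + n1 * gini_impurity(pos1, n1)) / n
        dec = parent - child
        if best_item is None or dec > best_dec + 1e-12:
            if dec > 1e-12:
                best_item, best_dec = item, dec
    if best_item is None:
        return None
    return best_item, best_dec


def _classify(n_pos: int, n: int, baseline: float, rule: str) -> str:
    frac = n_pos / n
    threshold = baseline if rule == "prevalence" else 0.5
    return "high" if frac >= threshold else "low"


def fit_tree(
    table: pd.DataFrame,
    items: Sequence[str],
    outcomes=None,
    params: CartParams | None = None,
) -> TreeNode:
    """Grow a classification tree on binary items by recursive Gini splitting.

    Recursion stops only when a node is pure, no candidate item both varies
    and improves impurity, or the optional depth/size limits are reached.
    Deterministic given its inputs.
    """
    if params is None:
        params = CartParams()
    y = pd.Series(table["outcome"] if outcomes is None else outcomes).reset_index(drop=True)
    mat = table[list(items)].reset_index(drop=True)
    n_pos_total = int(y.sum())
    if n_pos_total == 0 or n_pos_total == len(y):
        # constant outcome: a single leaf
        return TreeNode(
            n=len(y),
            n_positive=n_pos_total,
            depth=0,
            prediction="high" if n_pos_total == len(y) else "low",
        )
    baseline = n_pos_total / len(y)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yk = y.iloc[idx]
        n = len(idx)
        n_pos = int(yk.sum())
        node = TreeNode(
            n=n,
            n_positive=n_pos,
            depth=depth,
            prediction=_classify(n_pos, n, baseline, params.classify),
        )
        if n_pos == 0 or n_pos == n:
            return node
        if params.max_depth is not None and depth >= params.max_depth:
            return node
        if n < 2 * params.min_node_size:
            return node
        found = best_split(mat.iloc[idx], yk, items)
        if found is None:
            return node
        item, _ = found
        col = mat[item].iloc[idx]
        observed = col.notna()
        left_idx = idx[(observed & (col == 0)).to_numpy()]
        right_idx = idx[(observed & (col == 1)).to_numpy()]
        if len(left_idx) < params.min_node_size or len(right_idx) < params.min_node_size:
            return node
        node.split_item = item
        node.left = grow(left_idx, depth + 1)
        node.right = grow(right_idx, depth + 1)
        return node

    return grow(np.arange(len(y)), 0)


def predict_tree(tree: TreeNode, table: pd.DataFrame) -> pd.DataFrame:
    """Route each episode down the tree.

    Returns a frame with the predicted risk class and the positive fraction
    of the terminal node reached (used as the ROC score). Rows missing a
    split variable stop at that node.
    """
    needed = set()

    def collect(node: TreeNode) -> None:
        if node.split_item is not None:
            needed.add(node.split_item)
            collect(node.left)
            collect(node.right)

    collect(tree)
    missing_cols = needed - set(table.columns)
    if missing_cols:
        raise ConfigurationError(f"table lacks split items {sorted(missing_cols)}")

    classes = []
    scores = []
    for _, row in table.iterrows():
        node = tree
        while node.split_item is not None:
            val = row[node.split_item]
            if pd.isna(val):
                break
            node = node.right if int(val) == 1 else node.left
        classes.append(node.prediction)
        scores.append(node.positive_fraction)
    return pd.DataFrame(
        {"prediction": classes, "score": scores}, index=table.index
    )


def tree_accuracy(tree: TreeNode, table: pd.DataFrame, outcomes=None
                  ) -> tuple[AccuracyResult, AUCResult]:
    """Dual statistics of the tree's low/high classification plus ROC AUC.

    The AUC uses each episode's terminal-node positive fraction as its
    score, the standard way a fitted tree induces a ranking.
    """
    y = pd.Series(table["outcome"] if outcomes is None else outcomes).reset_index(drop=True)
    pred = predict_tree(tree, table.reset_index(drop=True))
    tab = two_by_two(pred["prediction"], y)
    return dual_statistics(tab), roc_auc(pred["score"], y)


# ---------------------------------------------------------------------------
# Serialization


def tree_to_dict(node: TreeNode) -> dict:
    out = {
        "n": node.n,
        "n_positive": node.n_positive,
        "depth": node.depth,
        "prediction": node.prediction,
        "positive_fraction": node.positive_fraction,
    }
    if node.split_item is not None:
        out["split_item"] = node.split_item
        out["left"] = tree_to_dict(node.left)
        out["right"] = tree_to_dict(node.right)
    return out


def tree_from_dict(raw: Mapping) -> TreeNode:
    node = TreeNode(
        n=raw["n"],
        n_positive=raw["n_positive"],
        depth=raw["depth"],
        prediction=raw["prediction"],
    )
    if "split_item" in raw:
        node.split_item = raw["split_item"]
        node.left = tree_from_dict(raw["left"])
        node.right = tree_from_dict(raw["right"])
    return node


def render_tree(node: TreeNode, indent: str = "") -> str:
    """Indented text rendering of the fitted tree."""
    head = (
        f"{indent}n={node.n} pos={node.n_positive} "
        f"({node.positive_fraction:.1%}) -> {node.prediction}"
    )
    if node.is_leaf:
        return head
    lines = [f"{head} | split on {node.split_item}"]
    lines.append(f"{indent}  [{node.split_item}=0]")
    lines.append(render_tree(node.left, indent + "    "))
    lines.append(f"{indent}  [{node.split_item}=1]")
    lines.append(render_tree(node.right, indent + "    "))
    return "\n".join(lines)


def tree_to_json(node: TreeNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(tree_to_dict(node), fh, indent=2)
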