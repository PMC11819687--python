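"""Ward/Euclidean hierarchical clustering with bootstrap node support.

Cultivar mean descriptor vectors are clustered agglomeratively (Ward linkage
on Euclidean distances).  Node stability is measured by a plain bootstrap:
leaf-level rows are resampled with replacement within cultivar, per-cultivar
means recomputed, the tree rebuilt, and a reference node counts as
reproduced in a replicate when some replicate node's leaf set reaches a
Jaccard similarity >= the threshold (default 0.8) with it.  Support is the
percentage of replicates reproducing the node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = ["DendrogramNode", "ward_tree", "bootstrap_support", "to_newick",
           "jaccard", "node_leaf_sets"]


@dataclass
class DendrogramNode:
    """A node of the merge tree; leaves carry a label, internal nodes two
    children, a merge height and (optionally) a bootstrap support percent."""
    label: Optional[str] = None
    children: Optional[List["DendrogramNode"]] = None
    height: float = 0.0
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaf_labels(self) -> FrozenSet[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaf_labels() for c in self.children))

    def internal_nodes(self) -> List["DendrogramNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label}
        return {"height": self.height, "support": self.support,
                "children": [c.to_dict() for c in self.children]}


def _vectors_to_matrix(vectors: Dict[str, Sequence[float]]):
    labels = list(vectors)
    if len(labels) < 2:
        raise ValueError("need at least 2 labeled vectors")
    dims = {len(vectors[l]) for l in labels}
    if len(dims) != 1:
        raise ValueError("vectors have mismatched dimensions")
    X = np.asarray([np.asarray(vectors[l], dtype=float) for l in labels])
    if not np.all(np.isfinite(X)):
        raise ValueError("vectors contain non-finite values")
    return labels, X


def ward_tree(vectors: Dict[str, Sequence[float]]) -> DendrogramNode:
    """Agglomerative Ward merge tree over labelled vectors (Euclidean)."""
    labels, X = _vectors_to_matrix(vectors)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    root, _ = hierarchy.to_tree(Z, rd=True)

    def build(node) -> DendrogramNode:
        if node.is_leaf():
            return DendrogramNode(label=labels[node.id])
        return DendrogramNode(children=[build(node.left), build(node.right)],
                              height=float(node.dist))

    return build(root)


def jaccard(a: FrozenSet[str], b: FrozenSet[str]) -> float:
    """Jaccard similarity |a & b| / |a | b| between two leaf sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def node_leaf_sets(tree: DendrogramNode) -> List[FrozenSet[str]]:
    """Leaf sets of every internal node of the tree."""
    return [n.leaf_labels() for n in tree.internal_nodes()]


def _cultivar_means(table: pd.DataFrame, label_col: str,
                    value_cols: Sequence[str]) -> Dict[str, np.ndarray]:
    means = table.groupby(label_col)[list(value_cols)].mean()
    return {str(i): means.loc[i].to_numpy() for i in means.index}


def bootstrap_support(raw_table: pd.DataFrame, value_cols: Sequence[str],
                      label_col: str = "cultivar", B: int = 100,
                      jaccard_threshold: float = 0.8,
                      seed: int = 0) -> DendrogramNode:
    """Reference Ward tree of per-cultivar means, annotated with bootstrap
    support percentages.

    Rows are resampled with replacement within cultivar for each of the B
    replicates; support of a reference node = 100 x (number of replicates
    containing a node whose leaf set matches it at Jaccard >= threshold) / B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < jaccard_threshold <= 1:
        raise ValueError("jaccard_threshold must lie in (0, 1]")
    counts = raw_table.groupby(label_col).size()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"every cultivar needs >= 2 rows; too few: {small}")

    ref = ward_tree(_cultivar_means(raw_table, label_col, value_cols))
    ref_nodes = ref.internal_nodes()
    ref_sets = [n.leaf_labels() for n in ref_nodes]
    reproduced = np.zeros(len(ref_sets), dtype=int)

    rng = np.random.default_rng(seed)
    groups = {str(k): g[list(value_cols)].to_numpy()
              for k, g in raw_table.groupby(label_col)}
    for _ in range(B):
        vectors = {}
        for cult, arr in groups.items():
            idx = rng.integers(0, arr.shape[0], size=arr.shape[0])
            vectors[cult] = arr[idx].mean(axis=0)
        rep_sets = node_leaf_sets(ward_tree(vectors))
        for i, rset in enumerate(ref_sets):
            if any(jaccard(rset, s) >= jaccard_threshold for s in rep_sets):
                reproduced[i] += 1
    for node, k in zip(ref_nodes, reproduced):
        node.support = 100.0 * k / B
    return ref


def _quote_label(label: str) -> str:
    meta = set("();:,[]' \t\n")
    if any(c in meta for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: DendrogramNode) -> str:
    """Newick serialization with branch lengths from merge heights and
    internal-node labels carrying the support percentage (if set)."""

    def render(node: DendrogramNode, parent_height: float) -> str:
        branch = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{_quote_label(node.label)}:{branch:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        sup = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){sup}:{branch:g}"

    if tree.is_leaf:
        return f"{_quote_label(tree.label)}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    sup = "" if tree.support is None else f"{tree.support:g}"
    return f"({inner}){sup};"
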