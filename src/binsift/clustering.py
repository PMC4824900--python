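"""Hierarchical organization of splits for curation.

Splits are clustered on a feature matrix with two blocks:

* **composition** — the 136 canonical tetranucleotide frequencies, used
  as-is (they are already on a common scale and sum to one per split);
* **coverage** — one column per DNA library holding ``log10(mean+1)``
  coverage, min-max scaled to [0, 1] per column and globally reweighted by
  ``sqrt(n_composition / n_samples)`` so the two blocks carry comparable
  aggregate weight in Euclidean distance.

The default mode combines both blocks (first-pass curation of a mixed
assembly); ``composition_only`` re-clusters a subset on composition alone
for finer second-pass curation.  RNA libraries never enter the features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .contigs import ContigsTable
from .profiling import CoverageMatrixSet

__all__ = [
    "FeatureMatrix",
    "SplitTree",
    "build_feature_matrix",
    "cluster_splits",
    "cut_tree",
    "export_newick",
    "load_newick",
]


@dataclass
class FeatureMatrix:
    """Splits x features matrix with per-column block labels."""

    values: pd.DataFrame
    block_labels: pd.Series  # column -> {"composition", "coverage"}

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("feature matrix contains NaN/Inf")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate split names in feature matrix")
        if not self.block_labels.index.equals(self.values.columns):
            raise ValueError("block_labels must label every column")

    @property
    def split_names(self) -> list[str]:
        return list(self.values.index)


@dataclass
class SplitTree:
    """Rooted binary tree over splits from agglomerative clustering.

    Wraps a scipy linkage matrix together with the leaf names; heights are
    cophenetic merge distances.
    """

    leaf_names: list[str]
    linkage_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.leaf_names[i] for i in order]


def build_feature_matrix(contigs: ContigsTable, coverage: CoverageMatrixSet | None = None,
                         mode: str = "combined") -> FeatureMatrix:
    """Assemble clustering features from composition and (optionally) coverage."""
    if mode not in ("combined", "composition_only"):
        raise ValueError(f"unknown mode {mode!r}")
    comp = contigs.tnf_matrix()
    if mode == "composition_only":
        labels = pd.Series("composition", index=comp.columns)
        return FeatureMatrix(values=comp, block_labels=labels)
    if coverage is None or not coverage.dna_samples:
        raise ValueError("combined mode requires coverage with at least one DNA sample")
    dna = coverage.dna_samples
    cov = np.log10(coverage.mean_matrix[dna].reindex(comp.index) + 1.0)
    rng_ = cov.max() - cov.min()
    scaled = (cov - cov.min()).div(rng_.replace(0.0, 1.0))  # constant column -> zeros
    weight = np.sqrt(comp.shape[1] / len(dna))
    scaled = scaled * weight
    values = pd.concat([comp, scaled], axis=1)
    labels = pd.Series(
        ["composition"] * comp.shape[1] + ["coverage"] * len(dna), index=values.columns
    )
    return FeatureMatrix(values=values, block_labels=labels)


def cluster_splits(matrix: FeatureMatrix, linkage: str = "ward",
                   metric: str = "euclidean") -> SplitTree:
    """Agglomerative clustering of splits; deterministic for fixed input."""
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering requires at least 2 splits")
    dists = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage)
    return SplitTree(leaf_names=matrix.split_names, linkage_matrix=Z)


def cut_tree(tree: SplitTree, k: int) -> dict[str, int]:
    """Cut into ``k`` flat clusters by removing the k-1 highest merges.

    Cluster ids are renumbered 1..k by order of first appearance along the
    leaf list, so the labeling is stable and readable.
    """
    if not (1 <= k <= tree.n_leaves):
        raise ValueError(f"k must be in [1, {tree.n_leaves}], got {k}")
    raw = hierarchy.fcluster(tree.linkage_matrix, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for name, lab in zip(tree.leaf_names, raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[name] = remap[lab]
    return out


def _needs_quoting(name: str) -> bool:
    return any(c in name for c in "()[]{}:;,' \t\n")


def _quote(name: str) -> str:
    if _needs_quoting(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: SplitTree) -> str:
    """Render the split tree as a newick string with branch lengths."""
    root = hierarchy.to_tree(tree.linkage_matrix)
    names = tree.leaf_names

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{_quote(names[node.id])}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(root, root.dist) + ";"


def export_newick(tree: SplitTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def load_newick(path: str | Path):
    """Read a newick file into a dendropy tree (for round-trip checks)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
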