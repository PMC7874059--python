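"""Categorical UPGMA clustering of STs and carbon-source phenotype clustering.

ST dendrograms use the categorical distance (fraction of mismatched
loci) and unweighted average linkage; merge heights are half the merge
distance, so cophenetic distances reproduce the merge distances and the
tree is ultrametric by construction.  Phenotype dendrograms use the
same machinery on a Manhattan distance over ternary 49-well carbon
utilisation scores (negative 0, weak positive 0.5, positive 1), which
preserves the weak-positive category; a Jaccard-on-binarised variant
is available.  Genotype/phenotype concordance between tree cuts is
summarised by the Adjusted Rand Index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .burst import profile_distance

__all__ = [
    "DistanceMatrix",
    "DendroNode",
    "categorical_distance",
    "upgma",
    "to_newick",
    "cut_tree",
    "cophenetic",
    "PhenotypeMatrix",
    "phenotype_distance",
    "partition_concordance",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0) or (m < 0).any():
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "matrix", m)

    def get(self, a, b) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def categorical_distance(profiles: Mapping[object, Sequence[int]]) -> DistanceMatrix:
    """Fraction of mismatched loci between every pair of profiles."""
    labels = tuple(profiles)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = profile_distance(profiles[a], profiles[labels[j]]) / len(profiles[a])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


@dataclass(frozen=True)
class DendroNode:
    """Binary dendrogram node; leaves carry a label, internal nodes a height."""

    height: float
    label: object = None
    left: Optional["DendroNode"] = None
    right: Optional["DendroNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


def upgma(d: DistanceMatrix) -> DendroNode:
    """Unweighted average-linkage agglomeration with lexicographic tie-break.

    Cluster pair distances update as size-weighted means; the merge
    height is merge distance / 2.  Among equally close pairs, the pair
    whose (smallest-member, smallest-member) string keys sort first is
    merged, making the tree deterministic.
    """
    if len(d.labels) < 2:
        raise ValueError("UPGMA needs >= 2 labels")
    nodes: dict[object, DendroNode] = {
        lab: DendroNode(height=0.0, label=lab) for lab in d.labels
    }
    sizes = {lab: 1 for lab in d.labels}
    keys = {lab: str(lab) for lab in d.labels}  # lexicographic identity of a cluster
    dist = {
        frozenset((a, b)): d.matrix[i, j]
        for i, a in enumerate(d.labels)
        for j, b in enumerate(d.labels)
        if i < j
    }
    active = list(d.labels)
    while len(active) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], tuple(sorted((keys[a], keys[b]))), a, b)
                for i, a in enumerate(active)
                for b in active[i + 1:]
            ),
        )
        dmin, _, a, b = best
        merged = DendroNode(height=dmin / 2.0, left=nodes[a], right=nodes[b])
        new = object()  # unique cluster handle
        nodes[new] = merged
        sizes[new] = sizes[a] + sizes[b]
        keys[new] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((new, c))] = (sizes[a] * dac + sizes[b] * dbc) / sizes[new]
        del dist[frozenset((a, b))]
        active = [c for c in active if c not in (a, b)] + [new]
    return nodes[active[0]]


def to_newick(node: DendroNode, precision: int = 10) -> str:
    """Newick string with branch lengths parent-height minus child-height."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}f}".rstrip("0").rstrip(".") or "0"

    def render(n: DendroNode, parent_height: float) -> str:
        bl = fmt(parent_height - n.height)
        if n.is_leaf:
            return f"{n.label}:{bl}"
        return f"({render(n.left, n.height)},{render(n.right, n.height)}):{bl}"

    return f"({render(node.left, node.height)},{render(node.right, node.height)});"


def cut_tree(node: DendroNode, k: int) -> dict:
    """Label -> cluster id for the k-cluster cut (split highest merges first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    clusters = [node]
    while len(clusters) < k:
        internal = [c for c in clusters if not c.is_leaf]
        if not internal:
            break
        tallest = max(internal, key=lambda c: c.height)
        clusters.remove(tallest)
        clusters.extend([tallest.left, tallest.right])
    return {leaf: i for i, c in enumerate(clusters) for leaf in c.leaves()}


def cophenetic(node: DendroNode) -> DistanceMatrix:
    """Pairwise cophenetic distances (2x the height of the lowest common merge)."""
    labels = tuple(node.leaves())
    idx = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))

    def walk(n: DendroNode) -> list:
        if n.is_leaf:
            return [n.label]
        left, right = walk(n.left), walk(n.right)
        for a in left:
            for b in right:
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = 2.0 * n.height
        return left + right

    walk(node)
    return DistanceMatrix(labels, m)


TERNARY_SCORES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Per-strain carbon-source utilisation scores, one column per well."""

    data: pd.DataFrame  # strains x wells, values in {0, 0.5, 1}
    reading_time: str = "48h"

    def __post_init__(self) -> None:
        vals = set(np.unique(self.data.to_numpy()))
        if not vals <= set(TERNARY_SCORES):
            raise ValueError(f"well scores must be in {TERNARY_SCORES}, got {sorted(vals)}")
        if self.data.isna().any().any():
            raise ValueError("phenotype matrix has missing wells")

    @property
    def n_wells(self) -> int:
        return self.data.shape[1]


def phenotype_distance(m: PhenotypeMatrix, metric: str = "manhattan") -> DistanceMatrix:
    """Pairwise phenotype distance in [0, 1].

    ``manhattan`` sums absolute ternary score differences / n_wells
    (default, keeps weak positives at half weight); ``jaccard``
    binarises weak positives to positive first.
    """
    x = m.data.to_numpy(dtype=float)
    if metric == "manhattan":
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2) / m.n_wells
    elif metric == "jaccard":
        b = x >= 0.5
        union = (b[:, None, :] | b[None, :, :]).sum(axis=2)
        inter = (b[:, None, :] & b[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(m.data.index), d)


def partition_concordance(cut_a: Mapping, cut_b: Mapping) -> float:
    """Adjusted Rand Index between two partitions of the same label set."""
    if set(cut_a) != set(cut_b):
        raise ValueError("partitions must cover the same labels")
    labels = sorted(cut_a, key=str)
    return float(adjusted_rand_score([cut_a[l] for l in labels],
                                     [cut_b[l] for l in labels]))
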