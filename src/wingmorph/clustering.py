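"""UPGMA hierarchical clustering of specimens by wing shape.

Clustering operates on Euclidean distances between full tangent shape
variables (equivalently, between complete PC score vectors: Euclidean
distance is identical in any orthonormal basis).  Inter-cluster distance is
the arithmetic mean over all cross-pairs, updated with the size-weighted
recurrence; merge height is half the merge distance, making the cophenetic
distances an ultrametric.  Ties among equally close pairs merge the
lexicographically smallest label pair, so trees are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform


def shape_distance_matrix(shape_variables: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix (zero diagonal, symmetric)."""
    X = np.asarray(shape_variables, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n >= 2, p) matrix of shape variables")
    return squareform(pdist(X))


@dataclass
class DendrogramNode:
    """A leaf (name set, no children) or an internal merge at a given height."""

    height: float
    name: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return self.children[0].leaves() + self.children[1].leaves()

    @property
    def size(self) -> int:
        return len(self.leaves())

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=self.height) + ";"

    def _newick_inner(self, parent_height: float) -> str:
        branch = parent_height - self.height
        if self.is_leaf:
            name = self.name.replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")
            return f"{name}:{branch:.10g}"
        left = self.children[0]._newick_inner(self.height)
        right = self.children[1]._newick_inner(self.height)
        return f"({left},{right}):{branch:.10g}"

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels and the matrix of heights at which each pair first joins."""
        labels = self.leaves()
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        mat = np.zeros((n, n))

        def walk(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = node.height
            return left + right

        walk(self)
        return labels, mat

    def cut(self, n_clusters: int) -> list[list[str]]:
        """Partition leaves into ``n_clusters`` by removing the highest merges."""
        if not 1 <= n_clusters <= self.size:
            raise ValueError("n_clusters out of range")
        clusters: list[DendrogramNode] = [self]
        while len(clusters) < n_clusters:
            tallest = max(
                (c for c in clusters if not c.is_leaf), key=lambda c: c.height, default=None
            )
            if tallest is None:
                break
            clusters.remove(tallest)
            clusters.extend(tallest.children)
        return [c.leaves() for c in clusters]


def upgma_tree(dist: np.ndarray, labels: list[str]) -> DendrogramNode:
    """Standard UPGMA agglomeration of a distance matrix.

    Iteratively merges the closest pair of clusters at height = distance / 2;
    the distance of the merged cluster to any other is the size-weighted mean
    of the two parents' distances (equal to the arithmetic mean over all
    cross-pairs of original specimens).
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix with n >= 2")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, name=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    # tie-break key: lexicographically smallest leaf label within the cluster
    minlab = {i: labels[i] for i in range(n)}
    work = D.copy()
    active = set(range(n))
    next_id = n
    ids = {i: i for i in range(n)}  # active id -> row index in work

    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                d = work[ids[a], ids[b]]
                key = (d, *sorted((minlab[a], minlab[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        d_ab = work[ids[a], ids[b]]
        merged = DendrogramNode(height=d_ab / 2.0, children=(nodes[a], nodes[b]))
        na, nb = sizes[a], sizes[b]
        row = np.empty(work.shape[0])
        for c in active:
            if c in (a, b):
                continue
            row[ids[c]] = (na * work[ids[a], ids[c]] + nb * work[ids[b], ids[c]]) / (na + nb)
        # reuse a's slot for the merged cluster
        slot = ids[a]
        for c in active:
            if c in (a, b):
                continue
            work[slot, ids[c]] = work[ids[c], slot] = row[ids[c]]
        active.discard(a)
        active.discard(b)
        nodes.pop(a), nodes.pop(b)
        nodes[next_id] = merged
        sizes[next_id] = na + nb
        minlab[next_id] = min(minlab[a], minlab[b])
        ids[next_id] = slot
        active.add(next_id)
        next_id += 1

    return nodes[next(iter(active))]
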