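"""Jaccard similarity and UPGMA grouping of restriction fingerprints.

Binary band profiles are compared with Jaccard's coefficient (joint absences
ignored), converted to distance 1 - J, and clustered with UPGMA (unweighted
pair-group method with arithmetic mean). Groups are read off by cutting the
dendrogram at a similarity threshold - 0.93 in the fingerprinting protocol
this package models - on the cophenetic distance scale, i.e. at distance
1 - s. Tie-breaking is by the lexicographically smallest cluster-label pair
so dendrograms are fully deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .util import ActinoprintError, ParameterError


class UndefinedSimilarityError(ActinoprintError, ValueError):
    """Jaccard similarity of two all-zero profiles (e.g. two empty lanes)."""


def jaccard(row_a, row_b) -> float:
    """Jaccard similarity a/(a+b+c) of two binary vectors.

    ``a`` counts shared presences, ``b`` and ``c`` presences unique to each
    row; joint absences carry no signal and are ignored. Undefined (raises)
    when both rows are all-zero.
    """
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("rows differ in length")
    union = int(np.sum(a | b))
    if union == 0:
        raise UndefinedSimilarityError("both profiles are all-zero")
    return int(np.sum(a & b)) / union


def jaccard_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Jaccard similarity of the rows of a binary matrix."""
    ids = list(matrix.index)
    vals = matrix.to_numpy(dtype=bool)
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = jaccard(vals[i], vals[j])
    return pd.DataFrame(sim, index=ids, columns=ids)


@dataclass
class Merge:
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    distance: float  # cophenetic distance (1 - similarity scale)


@dataclass
class Dendrogram:
    """UPGMA merge history; heights are cophenetic distances (1 - J)."""

    leaf_ids: list[str]
    merges: list[Merge] = field(default_factory=list)

    def cut_distance(self, max_distance: float) -> list[list[str]]:
        parent = {leaf: leaf for leaf in self.leaf_ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m in self.merges:
            if m.distance <= max_distance + 1e-12:
                ra, rb = find(m.members_a[0]), find(m.members_b[0])
                parent[rb] = ra
        groups: dict[str, list[str]] = {}
        for leaf in self.leaf_ids:
            groups.setdefault(find(leaf), []).append(leaf)
        return [sorted(g) for g in sorted(groups.values(), key=lambda g: min(g))]

    def to_treenode(self) -> TreeNode:
        """Rooted ultrametric tree; leaf heights are merge distance / 2."""
        height: dict[str, float] = {leaf: 0.0 for leaf in self.leaf_ids}
        node: dict[str, TreeNode] = {
            leaf: TreeNode(name=leaf) for leaf in self.leaf_ids
        }
        for m in self.merges:
            ka, kb = m.members_a[0], m.members_b[0]
            h = m.distance / 2.0
            na, nb = node[ka], node[kb]
            na.length = h - height[ka]
            nb.length = h - height[kb]
            merged = TreeNode(children=[na, nb])
            key = min(ka, kb)
            node[key] = merged
            height[key] = h
        roots = {id(v): v for v in node.values() if v.parent is None}
        root = next(iter(roots.values()))
        root.length = None
        return root


def upgma(similarities: pd.DataFrame) -> Dendrogram:
    """UPGMA on distance 1 - similarity with deterministic tie-breaking.

    At each step the closest cluster pair merges (ties by the smallest
    lexicographic pair of cluster labels, a cluster being labelled by its
    smallest leaf id); the distance between clusters is the arithmetic mean
    over all cross pairs of leaves (unweighted). Merge heights are
    guaranteed non-decreasing.
    """
    ids = list(similarities.index)
    if len(ids) < 2:
        raise ParameterError("need at least 2 profiles")
    vals = similarities.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ParameterError("similarity matrix is not symmetric")
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ParameterError("similarities must lie in [0, 1]")
    dist = 1.0 - vals
    index_of = {leaf: k for k, leaf in enumerate(ids)}
    clusters: dict[str, tuple[str, ...]] = {leaf: (leaf,) for leaf in ids}
    merges: list[Merge] = []
    last_height = 0.0
    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                la, lb = labels[x], labels[y]
                rows = [index_of[m] for m in clusters[la]]
                cols = [index_of[m] for m in clusters[lb]]
                d = float(dist[np.ix_(rows, cols)].mean())
                if best is None or d < best[0] - 1e-15:
                    best = (d, la, lb)
        d, la, lb = best
        merges.append(Merge(clusters[la], clusters[lb], d))
        assert d >= last_height - 1e-9, "UPGMA height inversion"
        last_height = max(last_height, d)
        merged = clusters.pop(la) + clusters.pop(lb)
        clusters[min(la, lb)] = merged
    return Dendrogram(leaf_ids=ids, merges=merges)


def cut_at_similarity(dend: Dendrogram, s: float) -> list[list[str]]:
    """Groups obtained by cutting the dendrogram at similarity ``s``.

    Leaves joined at cophenetic distance <= 1 - s form one group; at s = 1
    only identical profiles group, at s = 0 everything collapses.
    """
    if not 0.0 <= s <= 1.0:
        raise ParameterError("similarity threshold must be in [0, 1]")
    return dend.cut_distance(1.0 - s)


def fingerprint_report(
    matrix: pd.DataFrame, s: float = 0.93
) -> dict:
    """Distinct-fragment count and similarity groups for one band matrix.

    Returns ``{"distinct_fragments": #columns, "n_groups": int,
    "groups": list of id lists}`` using Jaccard + UPGMA + a cut at ``s``.
    """
    distinct = matrix.shape[1]
    if len(matrix) == 1:
        return {
            "distinct_fragments": distinct,
            "n_groups": 1,
            "groups": [list(matrix.index)],
        }
    groups = cut_at_similarity(upgma(jaccard_matrix(matrix)), s)
    return {"distinct_fragments": distinct, "n_groups": len(groups), "groups": groups}
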