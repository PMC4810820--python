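"""Comparing morphology, ecology and phylogeny: clustering and tree distance.

The downstream comparison machinery: species-mean score matrices, Euclidean
and Jaccard distance matrices, agglomerative clustering under five linkage
rules, majority-rule consensus dendrograms, and the path-difference metric
between unrooted tree topologies (with random resolution of polytomies,
since the metric is defined only for fully bifurcating trees).
"""

from __future__ import annotations

import itertools
import random as _random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform

import dendropy

__all__ = [
    "DistanceMatrix",
    "species_mean",
    "dist_matrix",
    "hcluster",
    "majority_consensus",
    "path_difference",
    "LINKAGES",
]

LINKAGES = ("ward", "single", "complete", "average", "mcquitty")


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def species_mean(scores: pd.DataFrame, species_col: str = "species") -> pd.DataFrame:
    """Average individual-level ordination scores within species.

    Row order follows first appearance of each species. Every row must carry
    a species label.
    """
    if species_col not in scores.columns:
        raise ValueError(f"missing {species_col!r} column")
    if scores[species_col].isna().any():
        raise ValueError("every individual must be labelled")
    out = scores.groupby(species_col, sort=False).mean(numeric_only=True)
    out.index.name = species_col
    return out


def dist_matrix(data: pd.DataFrame, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between rows.

    euclidean
        On a numeric matrix (e.g. species-averaged ordination scores).
    jaccard
        On a categorical trait table: traits are one-hot encoded (one
        indicator column per trait level) and the distance is
        ``1 - |A∩B| / |A∪B|`` over the levels each pair carries.
    """
    labels = list(data.index)
    if metric == "euclidean":
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("euclidean distances need a numeric matrix")
        cond = pdist(values, metric="euclidean")
    elif metric == "jaccard":
        if any(np.issubdtype(dt, np.number) for dt in data.dtypes):
            raise ValueError("jaccard distances need a categorical trait table")
        onehot = pd.get_dummies(data).to_numpy(dtype=bool)
        cond = pdist(onehot, metric="jaccard")
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return DistanceMatrix(labels=labels, matrix=squareform(cond))


def _linkage_to_tree(zmat: np.ndarray, labels) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace([str(x) for x in labels])
    nodes = []
    for i, lab in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(str(lab))
        nd.height = 0.0
        nodes.append(nd)
    for a, b, h, _cnt in zmat:
        nd = dendropy.Node()
        nd.height = float(h)
        for child in (nodes[int(a)], nodes[int(b)]):
            nd.add_child(child)
            child.edge.length = max(nd.height - child.height, 0.0)
        nodes.append(nd)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[-1]
    return tree


def hcluster(dist: DistanceMatrix, method: str = "average",
             ward_variant: str = "classic") -> dendropy.Tree:
    """Agglomerative clustering under a named linkage rule.

    ``mcquitty`` is WPGMA. ``ward`` defaults to the classic Lance-Williams
    recurrence applied to the unsquared distances (the behaviour of the
    clustering implementations contemporary with this pipeline's original
    environment); ``ward_variant="d2"`` selects the squared-distance variant
    instead. Returns the dendrogram as a rooted binary tree with merge
    heights as node depths.
    """
    if len(dist.labels) < 2:
        raise ValueError("need at least 2 labels")
    cond = dist.condensed
    if method == "mcquitty":
        zmat = _scipy_linkage(cond, method="weighted")
    elif method == "ward":
        if ward_variant == "classic":
            # Ward's update applied directly to the distances: run the
            # squared-variant machinery on sqrt(d) and square the heights.
            zmat = _scipy_linkage(np.sqrt(cond), method="ward")
            zmat = zmat.copy()
            zmat[:, 2] **= 2
        elif ward_variant == "d2":
            zmat = _scipy_linkage(cond, method="ward")
        else:
            raise ValueError(f"unknown ward variant: {ward_variant!r}")
    elif method in ("single", "complete", "average"):
        zmat = _scipy_linkage(cond, method=method)
    else:
        raise ValueError(f"unknown linkage: {method!r}")
    return _linkage_to_tree(zmat, dist.labels)


def _leafset(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _clades(tree: dendropy.Tree):
    """Non-trivial rooted clades (leaf-label sets) of a tree."""
    n = len(_leafset(tree))
    out = set()
    for node in tree.preorder_internal_node_iter():
        c = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(c) < n:
            out.add(c)
    return out


def majority_consensus(trees, p: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus of rooted dendrograms.

    Retains exactly the clades occurring in strictly more than ``p`` of the
    input trees (ties at the threshold are excluded), so the consensus may
    be multifurcating. All trees must share one leaf set.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    leafsets = [_leafset(t) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("trees must share an identical leaf set")
    leaves = sorted(leafsets[0])
    counts = {}
    for t in trees:
        for c in _clades(t):
            counts[c] = counts.get(c, 0) + 1
    kept = [c for c, k in counts.items() if k / len(trees) > p]
    # majority clades are pairwise nested-or-disjoint; build by containment
    kept.sort(key=len, reverse=True)
    ns = dendropy.TaxonNamespace(leaves)
    root = dendropy.Node()
    owner = {}  # leaf label -> deepest clade node containing it so far
    node_of = {}
    for lab in leaves:
        owner[lab] = root
    for c in kept:
        parents = {owner[lab] for lab in c}
        if len(parents) != 1:
            raise AssertionError("incompatible majority clades")
        parent = parents.pop()
        nd = dendropy.Node()
        parent.add_child(nd)
        node_of[c] = nd
        for lab in c:
            owner[lab] = nd
    for lab in leaves:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        owner[lab].add_child(nd)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    return tree


# ---------------------------------------------------------------------------
# Path difference between unrooted topologies
# ---------------------------------------------------------------------------


def _tree_to_graph(tree: dendropy.Tree):
    """Adjacency-list copy of a tree with degree-2 nodes spliced out.

    Splicing removes the root of a rooted binary dendrogram (and any other
    artefactual degree-2 node), yielding the unrooted topology.
    """
    adj = {}
    leaf_of = {}
    ids = {}

    def nid(node):
        if id(node) not in ids:
            ids[id(node)] = len(ids)
            adj[ids[id(node)]] = set()
        return ids[id(node)]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        adj[u].add(v)
        adj[v].add(u)
    for lf in tree.leaf_node_iter():
        leaf_of[nid(lf)] = lf.taxon.label
    # splice every internal degree-2 node
    changed = True
    while changed:
        changed = False
        for n in list(adj):
            if n in leaf_of or len(adj[n]) != 2:
                continue
            a, b = adj[n]
            adj[a].discard(n)
            adj[b].discard(n)
            adj[a].add(b)
            adj[b].add(a)
            del adj[n]
            changed = True
    return adj, leaf_of


def _resolve_polytomies(adj, leaf_of, rng):
    """Randomly resolve every node of degree > 3 into binary subtrees."""
    adj = {k: set(v) for k, v in adj.items()}
    next_id = max(adj) + 1
    for n in list(adj):
        if n in leaf_of:
            continue
        while len(adj[n]) > 3:
            a, b = rng.sample(sorted(adj[n]), 2)
            m = next_id
            next_id += 1
            for x in (a, b):
                adj[n].discard(x)
                adj[x].discard(n)
                adj[x].add(m)
            adj[m] = {a, b, n}
            adj[n].add(m)
    return adj


def _path_vector(adj, leaf_of):
    """Edge-count distances between all leaf pairs, in sorted-pair order."""
    labels = sorted(leaf_of.values())
    node_by_label = {lab: n for n, lab in leaf_of.items()}
    dist = {}
    for lab in labels:
        src = node_by_label[lab]
        seen = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + 1
                        nxt.append(v)
            frontier = nxt
        dist[lab] = seen
    return np.array([
        dist[a][node_by_label[b]]
        for a, b in itertools.combinations(labels, 2)
    ], dtype=np.float64)


def _is_binary(adj, leaf_of) -> bool:
    return all(len(adj[n]) == 3 for n in adj if n not in leaf_of)


def path_difference(t1: dendropy.Tree, t2: dendropy.Tree,
                    n_rep: int = 2000, seed: int | None = None) -> float:
    """Mean path difference between two unrooted leaf-labelled topologies.

    Each tree is represented by its vector of leaf-pair path lengths (edge
    counts, branch lengths ignored); the path difference is the Euclidean
    distance between the two vectors. Multifurcating trees are resolved
    uniformly at random ``n_rep`` times and the average difference is
    returned (one replicate suffices when both trees are binary).
    """
    g1, l1 = _tree_to_graph(t1)
    g2, l2 = _tree_to_graph(t2)
    if set(l1.values()) != set(l2.values()):
        raise ValueError("trees must share an identical leaf set")
    binary = _is_binary(g1, l1) and _is_binary(g2, l2)
    reps = 1 if binary else n_rep
    rng = _random.Random(seed)
    total = 0.0
    for _ in range(reps):
        a1 = g1 if _is_binary(g1, l1) else _resolve_polytomies(g1, l1, rng)
        a2 = g2 if _is_binary(g2, l2) else _resolve_polytomies(g2, l2, rng)
        v1 = _path_vector(a1, l1)
        v2 = _path_vector(a2, l2)
        total += float(np.sqrt(((v1 - v2) ** 2).sum()))
    return total / reps
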