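"""Hierarchical density-based clustering with condensed-tree persistence.

HDBSCAN in five steps: (1) per-point core distance (distance to the
``min_samples``-th nearest neighbour, self included); (2) mutual-reachability
distance ``max(core_i, core_j, d_ij)``; (3) minimum spanning tree of the
mutual-reachability graph; (4) single-linkage hierarchy from the sorted MST
edges, *condensed* by ``min_cluster_size``: a split only creates new clusters
when both branches are large enough, otherwise the small branch's points
simply "fall out" of the running cluster at that density level
(lambda = 1 / distance); (5) excess-of-mass selection of the most stable
clusters, where the stability of a cluster born at lambda_birth is
``sum_p (lambda_p - lambda_birth)`` over the lambdas at which its points
leave it.

Points that fall out of the hierarchy above every selected cluster are
outliers (label -1).  The per-cluster *persistence* reported here is the
stability normalised to [0, 1]:

    persistence = sum_p (lambda_p - lambda_birth)
                  / (n_p * (lambda_max - lambda_birth))

i.e. the mean lifetime of the cluster's points relative to the cluster's
total lambda span; 1 means every member survives to the cluster's maximum
density, 0 means the cluster evaporates at birth.

Exposed clusters are numbered 0..k-1 in the order their branches appear as
the distance threshold decreases (birth lambda ascending).  In the condensed
tree table, points keep ids 0..n-1 and condensed clusters are numbered from n
upward with the root cluster = n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

_LAMBDA_CAP = 1e10
_DIST_FLOOR = 1.0 / _LAMBDA_CAP

TREE_COLUMNS = ("parent", "child", "lam", "child_size")


@dataclass
class DensityClustering:
    """Labels (-1 = outlier), per-cluster persistence, and the condensed tree."""

    labels: np.ndarray
    persistence: dict[int, float]
    condensed_tree: pd.DataFrame


def _empty_tree() -> pd.DataFrame:
    return pd.DataFrame({c: [] for c in TREE_COLUMNS})


def _mutual_reachability(X: np.ndarray, min_samples: int) -> np.ndarray:
    D = squareform(pdist(X))
    k = min(min_samples, X.shape[0]) - 1  # self sits at sorted index 0
    core = np.partition(D, k, axis=1)[:, k]
    mreach = np.maximum(D, np.maximum.outer(core, core))
    np.fill_diagonal(mreach, 0.0)
    return mreach


def _mst_edges(mreach: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MST edge list sorted by weight; zero-weight edges survive via an offset."""
    n = mreach.shape[0]
    shift = 1e-9
    graph = csr_matrix(mreach + shift * (1.0 - np.eye(n)))
    mst = minimum_spanning_tree(graph).tocoo()
    weights = np.clip(mst.data - shift, 0.0, None)
    order = np.argsort(weights, kind="stable")
    return mst.row[order], mst.col[order], weights[order]


def _single_linkage(
    u: np.ndarray, v: np.ndarray, w: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Union-find agglomeration; returns (left, right, dist, size) per internal node."""
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    left = np.empty(n - 1, dtype=np.int64)
    right = np.empty(n - 1, dtype=np.int64)
    dist = np.empty(n - 1)
    size = np.ones(2 * n - 1, dtype=np.int64)
    node = n
    for a, b, weight in zip(u, v, w):
        ra, rb = find(int(a)), find(int(b))
        left[node - n], right[node - n] = ra, rb
        dist[node - n] = weight
        size[node] = size[ra] + size[rb]
        parent[ra] = parent[rb] = node
        node += 1
    return left, right, dist, size


def _leaves_under(node: int, left: np.ndarray, right: np.ndarray, n: int) -> list[int]:
    leaves: list[int] = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur < n:
            leaves.append(cur)
        else:
            stack.extend((left[cur - n], right[cur - n]))
    return leaves


def _condense(
    left: np.ndarray,
    right: np.ndarray,
    dist: np.ndarray,
    size: np.ndarray,
    n: int,
    min_cluster_size: int,
) -> pd.DataFrame:
    """Collapse the single-linkage dendrogram into the condensed cluster tree."""
    records: list[tuple[int, int, float, int]] = []
    root_node = 2 * n - 2
    next_cluster = n + 1
    stack: list[tuple[int, int]] = [(root_node, n)]  # (linkage node, condensed cluster)
    while stack:
        node, cluster = stack.pop()
        if node < n:
            continue
        i = node - n
        lam = 1.0 / max(dist[i], _DIST_FLOOR)
        l, r = int(left[i]), int(right[i])
        sl, sr = int(size[l]), int(size[r])
        big_l, big_r = sl >= min_cluster_size, sr >= min_cluster_size
        if big_l and big_r:
            for child, s in ((l, sl), (r, sr)):
                records.append((cluster, next_cluster, lam, s))
                stack.append((child, next_cluster))
                next_cluster += 1
        else:
            for child, big in ((l, big_l), (r, big_r)):
                if big:
                    stack.append((child, cluster))
                else:
                    for p in _leaves_under(child, left, right, n):
                        records.append((cluster, p, lam, 1))
    return pd.DataFrame(records, columns=list(TREE_COLUMNS))


def _stability(tree: pd.DataFrame, n: int) -> dict[int, float]:
    births: dict[int, float] = {n: 0.0}
    for row in tree.itertuples(index=False):
        if row.child >= n:
            births[int(row.child)] = float(row.lam)
    stab = {c: 0.0 for c in births}
    for row in tree.itertuples(index=False):
        parent = int(row.parent)
        stab[parent] += (min(float(row.lam), _LAMBDA_CAP) - births[parent]) * int(
            row.child_size
        )
    return stab


def _excess_of_mass(tree: pd.DataFrame, stability: dict[int, float], n: int) -> set[int]:
    """Select the most stable antichain of clusters; the root is never selected."""
    children: dict[int, list[int]] = {}
    for row in tree.itertuples(index=False):
        if row.child >= n:
            children.setdefault(int(row.parent), []).append(int(row.child))
    selected: set[int] = set()
    subtree_stab: dict[int, float] = {}
    for cluster in sorted(stability, reverse=True):
        if cluster == n:
            continue
        kids = children.get(cluster, [])
        kid_total = sum(subtree_stab[k] for k in kids)
        if not kids or stability[cluster] >= kid_total:
            # deselect every selected descendant
            stack = list(kids)
            while stack:
                c = stack.pop()
                selected.discard(c)
                stack.extend(children.get(c, []))
            selected.add(cluster)
            subtree_stab[cluster] = stability[cluster]
        else:
            subtree_stab[cluster] = kid_total
    return selected


def hdbscan_cluster(
    coords: np.ndarray, min_cluster_size: int, min_samples: int | None = None
) -> DensityClustering:
    """Run density clustering on a coordinate matrix.

    Returns labels per point (-1 outliers, 0..k-1 clusters numbered in
    detection order), per-cluster persistence, and the condensed tree.
    """
    X = np.asarray(coords, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("coords must be a nonempty 2-D array")
    if min_cluster_size < 2:
        raise ValidationError("min_cluster_size must be >= 2")
    n = X.shape[0]
    if min_samples is None:
        min_samples = min_cluster_size
    if n < min_cluster_size:
        warnings.warn(
            f"{n} points < min_cluster_size={min_cluster_size}; labelling all as outliers",
            stacklevel=2,
        )
        return DensityClustering(
            labels=np.full(n, -1), persistence={}, condensed_tree=_empty_tree()
        )

    mreach = _mutual_reachability(X, min_samples)
    if np.allclose(mreach, 0.0):
        # one degenerate dense mass: every point at the same position
        return DensityClustering(
            labels=np.zeros(n, dtype=np.int64),
            persistence={0: 1.0},
            condensed_tree=_empty_tree(),
        )
    u, v, w = _mst_edges(mreach)
    left, right, dist, size = _single_linkage(u, v, w, n)
    tree = _condense(left, right, dist, size, n, min_cluster_size)
    stability = _stability(tree, n)
    selected = _excess_of_mass(tree, stability, n)

    # cluster parent pointers for the walk-up from a point's fall-out cluster
    cluster_parent: dict[int, int] = {}
    births: dict[int, float] = {n: 0.0}
    for row in tree.itertuples(index=False):
        if row.child >= n:
            cluster_parent[int(row.child)] = int(row.parent)
            births[int(row.child)] = float(row.lam)

    ordered = sorted(selected, key=lambda c: (births[c], c))
    cluster_label = {c: i for i, c in enumerate(ordered)}

    labels = np.full(n, -1, dtype=np.int64)
    member_lams: dict[int, list[float]] = {c: [] for c in selected}
    for row in tree.itertuples(index=False):
        if row.child >= n:
            continue
        c = int(row.parent)
        while c is not None and c not in selected:
            c = cluster_parent.get(c)
        if c is not None:
            labels[int(row.child)] = cluster_label[c]
            member_lams[c].append(min(float(row.lam), _LAMBDA_CAP))

    persistence: dict[int, float] = {}
    for c in selected:
        lams = np.array(member_lams[c])
        span = lams.max() - births[c] if lams.size else 0.0
        if span <= 0.0:
            persistence[cluster_label[c]] = 0.0
        else:
            persistence[cluster_label[c]] = float(
                np.sum(lams - births[c]) / (lams.size * span)
            )
    return DensityClustering(labels=labels, persistence=persistence, condensed_tree=tree)
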