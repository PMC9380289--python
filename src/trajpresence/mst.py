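"""Euclidean minimum spanning tree on cluster centers and tree-shape statistics.

The shape of the MST built on the k cluster centers carries the trajectory
signal: a clean trajectory yields a path-like tree (few leaves, many
degree-two nodes, long diameter) while structureless data yield a branched,
compact tree.  Three integer statistics summarize the shape:

* ``D1`` — the number of leaves (degree-one nodes); minimized at 2 on a
  path graph, maximized at k-1 on a star tree.
* ``D2`` — the number of degree-two nodes; maximized at k-2 on a path
  graph, minimized at 0 on a star tree.
* ``Lmax`` — the length of a longest simple path, in edges (the unweighted
  tree diameter); k-1 on a path graph, 2 on a star tree.

Prim's algorithm builds the MST on the complete Euclidean graph.  Equal
edge weights are resolved deterministically — ties can change all three
statistics, so the tie rule is part of the contract, not a detail.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tree",
    "StatTriple",
    "build_mst",
    "count_degree_one",
    "count_degree_two",
    "longest_path_length",
    "stat_triple",
    "path_tree",
    "star_tree",
]


@dataclass(frozen=True)
class Tree:
    """A spanning tree: k nodes, k-1 weighted edges.

    Nodes are arbitrary hashable ids; edges are unordered id pairs with
    non-negative Euclidean weights.  Connectivity and acyclicity are
    checked on construction (a connected graph with k-1 edges is a tree).
    """

    nodes: tuple
    edges: tuple
    weights: tuple

    def __post_init__(self):
        nodes = tuple(self.nodes)
        edges = tuple((u, v) for u, v in self.edges)
        weights = tuple(float(w) for w in self.weights)
        k = len(nodes)
        if k < 2:
            raise ValueError("a tree needs at least 2 nodes")
        if len(set(nodes)) != k:
            raise ValueError("duplicate node ids")
        if len(edges) != k - 1:
            raise ValueError(f"a tree on {k} nodes needs {k - 1} edges, "
                             f"got {len(edges)}")
        if len(weights) != len(edges):
            raise ValueError("weights length != edges length")
        if any(w < 0 for w in weights):
            raise ValueError("negative edge weight")
        node_set = set(nodes)
        adj: dict = {v: [] for v in nodes}
        for u, v in edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            adj[u].append(v)
            adj[v].append(u)
        # k-1 edges + connected => acyclic
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != k:
            raise ValueError("graph is not connected")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "_adj", adj)

    @classmethod
    def from_edges(cls, edges, weights=None) -> "Tree":
        """Build a tree from an edge list; nodes are inferred and sorted."""
        edges = [tuple(e) for e in edges]
        nodes = sorted({v for e in edges for v in e})
        if weights is None:
            weights = [1.0] * len(edges)
        return cls(tuple(nodes), tuple(edges), tuple(weights))

    @property
    def k(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> float:
        return float(sum(self.weights))

    def degree(self, node) -> int:
        return len(self._adj[node])

    def degrees(self) -> dict:
        return {v: len(nbrs) for v, nbrs in self._adj.items()}

    def to_tsv(self, path: str) -> None:
        """Write the edge list as node_u <tab> node_v <tab> weight."""
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\n")
            for (u, v), w in zip(self.edges, self.weights):
                fh.write(f"{u}\t{v}\t{w!r}\n")


def path_tree(k: int) -> Tree:
    """The path graph 0-1-...-(k-1), unit weights."""
    return Tree.from_edges([(i, i + 1) for i in range(k - 1)])


def star_tree(k: int) -> Tree:
    """The star with hub 0 and k-1 spokes, unit weights."""
    return Tree.from_edges([(0, i) for i in range(1, k)])


def build_mst(centers) -> Tree:
    """Minimum spanning tree of the complete Euclidean graph on the centers.

    ``centers`` is a CenterSet or a k x d array; node ids are the row
    indices 0..k-1.  Prim's algorithm; among equal-weight candidate edges
    the one with the lexicographically smallest ``(min id, max id)`` pair
    wins, so duplicated centers and grid layouts give a deterministic tree.
    Duplicate centers are legal (zero-weight edges).
    """
    pts = np.asarray(getattr(centers, "centers", centers), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need a k x d array with k >= 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite center coordinates")
    k = pts.shape[0]
    sq = np.einsum("kd,kd->k", pts, pts)
    d2 = sq[:, None] + sq[None, :] - 2.0 * pts @ pts.T
    np.maximum(d2, 0.0, out=d2)
    dist = np.sqrt(d2)

    in_tree = np.zeros(k, dtype=bool)
    in_tree[0] = True
    best_w = dist[0].copy()
    best_parent = np.zeros(k, dtype=np.int64)
    edges = []
    weights = []
    for _ in range(k - 1):
        # select the out-node whose candidate edge minimizes the key
        # (weight, min pair id, max pair id)
        idx = np.flatnonzero(~in_tree)
        pmin = np.minimum(idx, best_parent[idx])
        pmax = np.maximum(idx, best_parent[idx])
        order = np.lexsort((pmax, pmin, best_w[idx]))
        v = int(idx[order[0]])
        u = int(best_parent[v])
        edges.append((min(u, v), max(u, v)))
        weights.append(float(dist[u, v]))
        in_tree[v] = True
        # relax: keep the better (weight, pair) candidate per out-node
        idx = np.flatnonzero(~in_tree)
        if idx.size:
            w_new = dist[v, idx]
            tie = w_new == best_w[idx]
            if np.any(tie):
                new_pmin = np.minimum(idx, v)
                new_pmax = np.maximum(idx, v)
                old_pmin = np.minimum(idx, best_parent[idx])
                old_pmax = np.maximum(idx, best_parent[idx])
                tie &= (new_pmin < old_pmin) | (
                    (new_pmin == old_pmin) & (new_pmax < old_pmax))
            upd = (w_new < best_w[idx]) | tie
            best_w[idx[upd]] = w_new[upd]
            best_parent[idx[upd]] = v
    return Tree(tuple(range(k)), tuple(edges), tuple(weights))


def count_degree_one(tree: Tree) -> int:
    """D1: the number of leaves (degree-one nodes)."""
    return sum(1 for d in tree.degrees().values() if d == 1)


def count_degree_two(tree: Tree) -> int:
    """D2: the number of degree-two nodes."""
    return sum(1 for d in tree.degrees().values() if d == 2)


def _bfs_farthest(tree: Tree, start) -> tuple:
    """(farthest node, hop distance) from ``start`` by BFS."""
    seen = {start: 0}
    queue = deque([start])
    far, far_d = start, 0
    while queue:
        u = queue.popleft()
        for v in tree._adj[u]:
            if v not in seen:
                seen[v] = seen[u] + 1
                if seen[v] > far_d:
                    far, far_d = v, seen[v]
                queue.append(v)
    return far, far_d


def longest_path_length(tree: Tree) -> int:
    """Lmax: edges in a longest simple path (the unweighted diameter).

    Two BFS sweeps: from an arbitrary node to its farthest node a, then
    from a; the second eccentricity is the diameter of a tree.
    """
    a, _ = _bfs_farthest(tree, tree.nodes[0])
    _, diameter = _bfs_farthest(tree, a)
    return diameter


@dataclass(frozen=True)
class StatTriple:
    """The observed (D1, D2, Lmax) for one tree.

    For k >= 3 nodes: 2 <= d1 <= k-1, 0 <= d2 <= k-2, 2 <= lmax <= k-1,
    and d1 = 2, d2 = k-2, lmax = k-1 are all equivalent to the tree being
    a path graph.
    """

    d1: int
    d2: int
    lmax: int

    def as_dict(self) -> dict:
        return {"D1": self.d1, "D2": self.d2, "Lmax": self.lmax}


def stat_triple(tree: Tree) -> StatTriple:
    """Compute all three tree-shape statistics in one pass."""
    degs = list(tree.degrees().values())
    return StatTriple(
        d1=sum(1 for d in degs if d == 1),
        d2=sum(1 for d in degs if d == 2),
        lmax=longest_path_length(tree),
    )
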