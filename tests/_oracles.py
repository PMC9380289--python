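"""Independent oracles used by the unit and acceptance tests.

These implementations deliberately share no code with the package: Kruskal
with union-find checks Prim, networkx BFS checks the two-sweep diameter,
and random Prüfer sequences enumerate labeled trees.
"""

from __future__ import annotations

import numpy as np


def kruskal_mst_weight(points: np.ndarray) -> float:
    """Total MST weight of the complete Euclidean graph, via Kruskal."""
    k = points.shape[0]
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = sorted(
        (float(np.linalg.norm(points[i] - points[j])), i, j)
        for i in range(k) for j in range(i + 1, k))
    total, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == k - 1:
                break
    return total


def random_prufer_edges(k: int, rng: np.random.Generator) -> list[tuple]:
    """Edge list of a uniform random labeled tree on k nodes."""
    import networkx as nx

    seq = [int(rng.integers(k)) for _ in range(k - 2)]
    return list(nx.from_prufer_sequence(seq).edges())


def bfs_diameter(edges: list[tuple]) -> int:
    """Tree diameter in edges by all-pairs BFS (networkx eccentricity)."""
    import networkx as nx

    g = nx.Graph(edges)
    return max(nx.eccentricity(g).values())
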