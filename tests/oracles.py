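"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: flow centrality
is recomputed by enumerating every minimal-length path with networkx,
and the topological overlap matrix by an explicit triple loop.
"""
from collections import Counter, defaultdict

import networkx as nx
import numpy as np


def brute_force_flow(graph, nodes_a, nodes_b):
    """Enumerate all shortest paths per module pair.

    Returns (fc_normalized, fc_raw, sigma_ab, sigma_ab_v) where
    sigma_ab_v maps (a, b, v) -> interior path count.
    """
    frac = defaultdict(float)
    raw = defaultdict(int)
    sigma = {}
    sigma_v = {}
    seen = set()
    for a in nodes_a:
        for b in nodes_b:
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            if not nx.has_path(graph, a, b):
                continue
            paths = list(nx.all_shortest_paths(graph, a, b))
            sigma[key] = len(paths)
            counts = Counter(v for p in paths for v in p[1:-1])
            for v, c in counts.items():
                frac[v] += c / len(paths)
                raw[v] += c
                sigma_v[(key, v)] = c
    norm = len(nodes_a) * len(nodes_b)
    fc = {v: frac.get(v, 0.0) / norm for v in graph.nodes}
    fc_raw = {v: raw.get(v, 0) for v in graph.nodes}
    return fc, fc_raw, sigma, sigma_v


def brute_force_tom(values, beta):
    """O(n^3) topological overlap from first principles."""
    n = values.shape[0]
    a = np.abs(np.corrcoef(values)) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def all_connected_labeled_graphs(n):
    """Yield every connected labeled simple graph on n nodes."""
    from itertools import combinations

    nodes = list(range(n))
    possible = list(combinations(nodes, 2))
    for mask in range(2 ** len(possible)):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(e for i, e in enumerate(possible) if mask >> i & 1)
        if nx.is_connected(g):
            yield g


def random_connected_gnp(n, p, rng):
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g
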