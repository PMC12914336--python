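"""Module-pair shortest distance and flow centrality on an interactome.

Two statistics rank candidate driver genes between a pair of disease
modules A and B on an undirected, unweighted interaction graph:

* module shortest distance
      d(A, B) = (1 / (|A| * |B|)) * sum_{a in A, b in B} d(a, b)
  reported as the mean over reachable pairs, with the reachable-pair
  fraction alongside;

* flow centrality of a node v
      FC_{A,B}(v) = (1 / (|A| * |B|)) * sum_{a, b} sigma_ab(v) / sigma_ab
  where sigma_ab counts shortest a-b paths and sigma_ab(v) those passing
  through v as an interior vertex (the standard betweenness endpoint
  convention: v in {a, b} contributes 0).

A per-node distance score (sum of shortest distances from v to every
module member) provides the "minimum shortest distance" ranking; the
top-k lists by maximum FC and minimum distance are intersected across
the three disease pairs to call common driver genes.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .datatypes import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePairDistance",
    "DriverScoreTable",
    "DriverCall",
    "shortest_path_counts",
    "module_pair_distance",
    "flow_centrality",
    "node_distance_sum",
    "screen_drivers",
]


@dataclass(frozen=True)
class ModulePairDistance:
    module_a: tuple[str, ...]
    module_b: tuple[str, ...]
    d_shortest: float  # mean over reachable pairs
    reachable_pair_fraction: float
    n_pairs: int
    n_reachable: int


@dataclass
class DriverScoreTable:
    """Per-node flow-centrality and distance scores for one module pair."""

    pair_name: tuple[str, str]
    module_a: tuple[str, ...]
    module_b: tuple[str, ...]
    scores: pd.DataFrame  # node, fc_normalized, fc_raw, distance_sum, ...
    distance: ModulePairDistance


@dataclass
class DriverCall:
    top_fc: dict[tuple[str, str], tuple[str, ...]]
    top_distance: dict[tuple[str, str], tuple[str, ...]]
    qualifying: dict[tuple[str, str], frozenset[str]]
    drivers: GeneSet
    k: int


def shortest_path_counts(graph: nx.Graph, source: str) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts sigma from one source."""
    if source not in graph:
        raise KeyError(f"source node {source!r} not in graph")
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in graph[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = sigma[u]
                queue.append(w)
            elif dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def _restrict(graph: nx.Graph, gs: GeneSet, label: str) -> list[str]:
    present = [g for g in gs.genes if g in graph]
    absent = len(gs.genes) - len(present)
    if absent:
        logger.warning("%s: dropped %d module genes absent from the graph", label, absent)
    if not present:
        raise ValueError(f"{label}: no module genes present in the graph")
    return present


def module_pair_distance(graph: nx.Graph, a: GeneSet, b: GeneSet) -> ModulePairDistance:
    """Mean shortest distance over all reachable (a, b) pairs.

    Pairs with a == b contribute distance 0; unreachable pairs are
    excluded from the mean and reported through the reachable fraction.
    """
    nodes_a = _restrict(graph, a, f"module {a.name}")
    nodes_b = _restrict(graph, b, f"module {b.name}")
    total = 0.0
    n_reachable = 0
    n_pairs = len(nodes_a) * len(nodes_b)
    for na in nodes_a:
        dist, _ = shortest_path_counts(graph, na)
        for nb in nodes_b:
            if nb in dist:
                total += dist[nb]
                n_reachable += 1
    if n_reachable == 0:
        raise ValueError("no reachable module pair; distance undefined")
    return ModulePairDistance(
        tuple(nodes_a),
        tuple(nodes_b),
        total / n_reachable,
        n_reachable / n_pairs,
        n_pairs,
        n_reachable,
    )


def _bfs_cache(graph: nx.Graph, nodes: Sequence[str]) -> dict[str, tuple[dict, dict]]:
    return {n: shortest_path_counts(graph, n) for n in dict.fromkeys(nodes)}


def flow_centrality(
    graph: nx.Graph,
    a: GeneSet,
    b: GeneSet,
    pair_name: tuple[str, str] = ("A", "B"),
) -> DriverScoreTable:
    """Score every node's flow centrality and distance sum for (A, B).

    Each unordered pair {a, b} with a in A, b in B, a != b is counted
    once; sigma_ab(v) = sigma_a(v) * sigma_b(v) when v lies on a
    shortest a-b path. fc_normalized divides the fractional sum by
    |A| * |B|; fc_raw is the unnormalized integer path-count sum
    sum sigma_ab(v). The distance_sum column is the per-node sum of
    finite distances to all members of A union B.
    """
    nodes_a = _restrict(graph, a, f"module {a.name}")
    nodes_b = _restrict(graph, b, f"module {b.name}")
    endpoints = list(dict.fromkeys(nodes_a + nodes_b))
    cache = _bfs_cache(graph, endpoints)

    all_nodes = sorted(graph.nodes)
    fc_frac = {v: 0.0 for v in all_nodes}
    fc_raw = {v: 0 for v in all_nodes}

    seen_pairs: set[frozenset[str]] = set()
    for na in nodes_a:
        da, sa = cache[na]
        for nb in nodes_b:
            if na == nb:
                continue
            key = frozenset((na, nb))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            if nb not in da:
                continue  # unreachable pair contributes 0
            d_ab = da[nb]
            sigma_ab = sa[nb]
            db, sb = cache[nb]
            for v in all_nodes:
                if v == na or v == nb:
                    continue
                dv_a = da.get(v)
                dv_b = db.get(v)
                if dv_a is None or dv_b is None or dv_a + dv_b != d_ab:
                    continue
                count = sa[v] * sb[v]
                fc_frac[v] += count / sigma_ab
                fc_raw[v] += count

    norm = len(nodes_a) * len(nodes_b)
    dist_sum, dist_reach = node_distance_sum(graph, a, b, _cache=cache)
    df = pd.DataFrame(
        {
            "node": all_nodes,
            "fc_normalized": [fc_frac[v] / norm for v in all_nodes],
            "fc_raw_fractional": [fc_frac[v] for v in all_nodes],
            "fc_raw": [fc_raw[v] for v in all_nodes],
            "distance_sum": [dist_sum[v] for v in all_nodes],
            "distance_reachable": [dist_reach[v] for v in all_nodes],
        }
    )
    fc_order = df.sort_values(["fc_normalized", "node"], ascending=[False, True]).index
    df["fc_rank"] = 0
    df.loc[fc_order, "fc_rank"] = range(1, len(fc_order) + 1)
    ranked = df[df["distance_reachable"] > 0]
    d_order = ranked.sort_values(["distance_sum", "node"], ascending=[True, True]).index
    df["distance_rank"] = 0  # 0 = unranked (no reachable member)
    df.loc[d_order, "distance_rank"] = range(1, len(d_order) + 1)

    distance = module_pair_distance(graph, a, b)
    return DriverScoreTable(pair_name, tuple(nodes_a), tuple(nodes_b), df, distance)


def node_distance_sum(
    graph: nx.Graph,
    a: GeneSet,
    b: GeneSet,
    _cache: dict | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-node sum of finite shortest distances to members of A union B.

    Returns (distance_sum, reachable_count); nodes reaching no member
    get sum 0 with reachable count 0 and must be flagged by callers
    before ranking.
    """
    nodes_a = [g for g in a.genes if g in graph]
    nodes_b = [g for g in b.genes if g in graph]
    endpoints = list(dict.fromkeys(nodes_a + nodes_b))
    cache = _cache or _bfs_cache(graph, endpoints)
    dist_sum = {v: 0 for v in graph.nodes}
    reach = {v: 0 for v in graph.nodes}
    for u in endpoints:
        du, _ = cache[u]
        for v, d in du.items():
            if v != u:
                dist_sum[v] += d
                reach[v] += 1
    return dist_sum, reach


def screen_drivers(
    tables: Mapping[tuple[str, str], DriverScoreTable] | Sequence[DriverScoreTable],
    k: int = 10,
) -> DriverCall:
    """Top-k screening per disease pair and cross-pair intersection.

    Per pair, the top-k nodes by maximum fc_normalized and the top-k by
    minimum distance_sum (nodes with no reachable member excluded) each
    qualify; common drivers are the genes qualifying in every pair.
    Ties break on (score, lexicographic node id).
    """
    if not isinstance(tables, Mapping):
        tables = {t.pair_name: t for t in tables}
    top_fc: dict[tuple[str, str], tuple[str, ...]] = {}
    top_dist: dict[tuple[str, str], tuple[str, ...]] = {}
    qualifying: dict[tuple[str, str], frozenset[str]] = {}
    for pair, table in tables.items():
        df = table.scores
        if len(df) < k:
            logger.warning("pair %s: only %d scored nodes (< k=%d)", pair, len(df), k)
        fc_sorted = df.sort_values(["fc_normalized", "node"], ascending=[False, True])
        top_fc[pair] = tuple(fc_sorted["node"].head(k))
        reachable = df[df["distance_reachable"] > 0]
        d_sorted = reachable.sort_values(["distance_sum", "node"], ascending=[True, True])
        top_dist[pair] = tuple(d_sorted["node"].head(k))
        qualifying[pair] = frozenset(top_fc[pair]) | frozenset(top_dist[pair])
    common = set.intersection(*(set(q) for q in qualifying.values())) if qualifying else set()
    return DriverCall(
        top_fc=top_fc,
        top_distance=top_dist,
        qualifying=qualifying,
        drivers=GeneSet.from_iterable("drivers", sorted(common)),
        k=k,
    )
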