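"""Brute-force reference implementations, independent of the package.

Everything here works from a plain edge list with elementary data
structures (adjacency sets, BFS queues, a dense Floyd–Warshall matrix,
explicit shortest-path enumeration) so it shares no code path with the
networkx-backed statistics it is used to verify.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def degrees_oracle(nodes, edges):
    adj = adjacency(nodes, edges)
    return {n: len(adj[n]) for n in nodes}


def clustering_oracle(nodes, edges):
    """Local clustering by counting realized links among neighbors."""
    adj = adjacency(nodes, edges)
    coeffs = {}
    for n in nodes:
        k = len(adj[n])
        if k < 2:
            coeffs[n] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(adj[n], key=repr), 2) if b in adj[a])
        coeffs[n] = 2.0 * links / (k * (k - 1))
    return coeffs


def components_oracle(nodes, edges):
    """Connected components via breadth-first search; list of frozensets."""
    adj = adjacency(nodes, edges)
    seen = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        queue = deque([start])
        comp = {start}
        seen.add(start)
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    queue.append(v)
        components.append(frozenset(comp))
    return components


def path_length_oracle(nodes, edges):
    """Mean shortest-path length over unordered pairs via Floyd–Warshall.

    Requires a connected graph with at least two nodes.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in edges:
        if a != b:
            dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    upper = dist[np.triu_indices(n, k=1)]
    assert np.all(np.isfinite(upper)), "path-length oracle needs a connected graph"
    return float(upper.mean())


def _all_shortest_paths(adj, dist, source, target):
    """Enumerate all shortest source→target paths over the predecessor DAG."""
    if dist.get(target) is None:
        return []
    paths = []
    stack = [(target, [target])]
    while stack:
        node, path = stack.pop()
        if node == source:
            paths.append(list(reversed(path)))
            continue
        for pred in adj[node]:
            if dist.get(pred) == dist[node] - 1:
                stack.append((pred, path + [pred]))
    return paths


def edge_betweenness_oracle(nodes, edges):
    """Raw edge betweenness by explicit enumeration of all shortest paths.

    Each unordered node pair contributes 1, split equally among its
    shortest paths; the contribution of a path is spread over its edges.
    """
    adj = adjacency(nodes, edges)
    result = {frozenset((a, b)): 0.0 for a, b in edges if a != b}
    nodelist = list(nodes)
    for i, s in enumerate(nodelist):
        # BFS distances from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t in nodelist[i + 1 :]:
            if t not in dist or t == s:
                continue
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for a, b in zip(path, path[1:]):
                    result[frozenset((a, b))] += share
    return result
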