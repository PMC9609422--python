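"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — explicit breadth-first searches,
full path enumeration, exhaustive combinatorial draws, repeated whole-graph
pruning — and shares no code with the package under test.
"""

from __future__ import annotations

import itertools
from collections import deque


def bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def closeness_by_bfs(adj: dict[str, set[str]]) -> dict[str, float]:
    """(m-1)/sum(dist) within each node's component; isolated nodes 0."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def _all_shortest_paths(adj, s, t):
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == s:
            paths.append(list(reversed(path + [s])))
            return
        for p in adj[node]:
            if dist.get(p, -1) == dist[node] - 1:
                walk(p, path + [node])

    walk(t, [])
    return paths


def betweenness_by_enumeration(
    adj: dict[str, set[str]], normalized: bool = True
) -> dict[str, float]:
    """Sum over unordered pairs of (shortest paths through v)/(all shortest
    paths), endpoints excluded, normalised per component size."""
    acc = {v: 0.0 for v in adj}
    comp_of: dict[str, frozenset[str]] = {}
    for v in adj:
        if v not in comp_of:
            comp = frozenset(bfs_distances(adj, v))
            for u in comp:
                comp_of[u] = comp
    for s, t in itertools.combinations(sorted(adj), 2):
        if comp_of[s] != comp_of[t]:
            continue
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for interior in path[1:-1]:
                acc[interior] += 1.0 / len(paths)
    if normalized:
        for v in adj:
            m = len(comp_of[v])
            acc[v] *= 2.0 / ((m - 1) * (m - 2)) if m >= 3 else 0.0
    return acc


def k_core_by_deletion(
    nodes: set[str], edges: set[frozenset[str]], k: int
) -> set[str]:
    """Delete low-degree nodes and restart from scratch until stable."""
    alive = set(nodes)
    while True:
        deg = {v: 0 for v in alive}
        for e in edges:
            a, b = tuple(e)
            if a in alive and b in alive:
                deg[a] += 1
                deg[b] += 1
        low = {v for v in alive if deg[v] < k}
        if not low:
            return alive
        alive -= low


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P[overlap >= k] by drawing every n-subset of an N-universe."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total
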