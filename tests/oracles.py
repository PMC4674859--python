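"""Naive independent reference implementations used as test oracles.

Everything here is deliberately brute force (nested loops, explicit path
enumeration, Floyd–Warshall) and shares no code with the package's
networkx-backed implementations.
"""

from __future__ import annotations

import itertools
import random

INF = float("inf")


def floyd_warshall(nodes: list, edges: set[frozenset]) -> dict[tuple, float]:
    dist = {(a, b): (0 if a == b else INF) for a in nodes for b in nodes}
    for e in edges:
        pair = tuple(e)
        a, b = pair if len(pair) == 2 else (pair[0], pair[0])
        dist[(a, b)] = dist[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[(i, k)] + dist[(k, j)] < dist[(i, j)]:
                    dist[(i, j)] = dist[(i, k)] + dist[(k, j)]
    return dist


def brute_components(nodes: list, edges: set[frozenset]) -> int:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for e in edges:
        pair = tuple(e)
        if len(pair) == 2:
            a, b = pair
            parent[find(a)] = find(b)
    return len({find(n) for n in nodes})


def brute_clustering(nodes: list, edges: set[frozenset]) -> float:
    """Mean over all nodes of 2e/(k(k-1)); k < 2 contributes 0."""
    if not nodes:
        return 0.0
    adj = {n: set() for n in nodes}
    for e in edges:
        pair = tuple(e)
        if len(pair) == 2:
            a, b = pair
            adj[a].add(b)
            adj[b].add(a)
    total = 0.0
    for n in nodes:
        nbrs = sorted(adj[n], key=str)
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        total += 2 * links / (k * (k - 1))
    return total / len(nodes)


def brute_path_stats(nodes: list, edges: set[frozenset]):
    """(diameter, characteristic path length) over connected pairs; None if none."""
    dist = floyd_warshall(nodes, edges)
    finite = [d for (a, b), d in dist.items() if a != b and d < INF]
    if not finite:
        return None, None
    return int(max(finite)), sum(finite) / len(finite)


def brute_betweenness(nodes: list, edges: set[frozenset]) -> dict:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    adj = {n: set() for n in nodes}
    for e in edges:
        pair = tuple(e)
        if len(pair) == 2:
            a, b = pair
            adj[a].add(b)
            adj[b].add(a)

    def all_paths(src, dst):
        paths = []

        def dfs(cur, path):
            if cur == dst:
                paths.append(tuple(path))
                return
            for nxt in adj[cur]:
                if nxt not in path:
                    path.append(nxt)
                    dfs(nxt, path)
                    path.pop()

        dfs(src, [src])
        return paths

    bc = {n: 0.0 for n in nodes}
    ordered = sorted(nodes, key=str)
    for i, s in enumerate(ordered):
        for t in ordered[i + 1:]:
            paths = all_paths(s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sps = [p for p in paths if len(p) == shortest]
            for p in sps:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(sps)
    return bc


def interval_union_components(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping (not merely touching) half-open intervals."""
    remaining = list(spans)
    merged = []
    while remaining:
        cur = remaining.pop()
        changed = True
        while changed:
            changed = False
            for other in list(remaining):
                if cur[0] < other[1] and other[0] < cur[1]:
                    cur = (min(cur[0], other[0]), max(cur[1], other[1]))
                    remaining.remove(other)
                    changed = True
        merged.append(cur)
    return sorted(merged)


def random_graph(rng: random.Random, max_nodes: int = 8):
    n = rng.randrange(1, max_nodes + 1)
    nodes = [("GENE", i) for i in range(n)]
    edges = set()
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < 0.35:
            edges.add(frozenset((a, b)))
    return nodes, edges
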