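"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, BFS from scratch,
log-factorial sums) and shares no code path with the package internals it
verifies.
"""

import itertools
import math
from collections import deque


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def to_adj(network) -> dict:
    return {v: set(network[v]) for v in network.nodes()}


def naive_ci(network, ell: int) -> dict:
    """Double loop over BFS level sets, straight from the definition."""
    adj = to_adj(network)
    deg = {v: len(adj[v]) for v in adj}
    out = {}
    for v in adj:
        if deg[v] == 0:
            out[v] = 0
            continue
        dist = bfs_distances(adj, v)
        frontier = [u for u, d in dist.items() if d == ell]
        out[v] = (deg[v] - 1) * sum(deg[u] - 1 for u in frontier)
    return out


def brute_betweenness(network) -> dict:
    """All-pairs enumeration of shortest paths (graphs of ~12 nodes)."""
    adj = to_adj(network)
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}

    def all_shortest_paths(s, t, dist):
        # depth-first expansion along edges that decrease distance-to-t
        dist_t = bfs_distances(adj, t)
        if t not in dist:
            return []
        paths = []
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                paths.append(path)
                continue
            for w in adj[u]:
                if dist_t.get(w, math.inf) == dist_t[u] - 1:
                    stack.append((w, path + [w]))
        return paths

    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t, dist)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def is_dominating(adj: dict, candidate: set) -> bool:
    return all(v in candidate or adj[v] & candidate for v in adj)


def brute_min_dominating(network):
    """(gamma, list of all minimum dominating sets) by subset enumeration."""
    adj = to_adj(network)
    nodes = sorted(adj)
    for k in range(1, len(nodes) + 1):
        sets = [frozenset(c) for c in itertools.combinations(nodes, k)
                if is_dominating(adj, set(c))]
        if sets:
            return k, sets
    raise AssertionError("V dominates itself")


def hypergeom_upper_tail(k: int, universe: int, n_annot: int, n_class: int) -> float:
    """P[overlap >= k] via explicit log-factorial point probabilities."""

    def log_comb(n, r):
        if r < 0 or r > n:
            return -math.inf
        return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    denom = log_comb(universe, n_class)
    total = 0.0
    for x in range(k, min(n_annot, n_class) + 1):
        lp = log_comb(n_annot, x) + log_comb(universe - n_annot, n_class - x) - denom
        if lp > -math.inf:
            total += math.exp(lp)
    return min(total, 1.0)


def ks_statistic_sweep(a, b) -> float:
    """sup |F_a - F_b| by stepping through every sample point."""
    a, b = sorted(a), sorted(b)
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d
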