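"""Hand-written brute-force oracles, independent of the library's graph code."""

import numpy as np


def _simple_paths(adj, s, t):
    """All simple directed paths s -> t by DFS on a 0/1 matrix."""
    n = len(adj)
    paths = []

    def dfs(node, visited, path):
        if node == t:
            paths.append(list(path))
            return
        for nxt in range(n):
            if adj[node][nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(s, {s}, [s])
    return paths


def brute_betweenness(adj):
    """Exhaustive shortest-path enumeration betweenness (unnormalized).

    For each ordered pair (s, t) with at least one path, every node strictly
    inside a shortest path earns 1/(number of shortest s->t paths).
    """
    adj = np.asarray(adj)
    n = len(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = _simple_paths(adj, s, t)
            if not paths:
                continue
            d = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == d]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def brute_in_degree(adj):
    """Independent column scan: distinct nominators per column."""
    adj = np.asarray(adj)
    n = len(adj)
    return np.array([sum(1 for j in range(n) if adj[j][k] > 0) for k in range(n)], dtype=float)


def brute_harmonic_out_closeness(adj):
    """(1/(n-1)) * sum of reciprocal shortest-path lengths from each node."""
    adj = np.asarray(adj)
    n = len(adj)
    out = np.zeros(n)
    for v in range(n):
        for u in range(n):
            if u == v:
                continue
            paths = _simple_paths(adj, v, u)
            if paths:
                out[v] += 1.0 / (min(len(p) for p in paths) - 1)
    return out / (n - 1)


def random_digraph(rng, n, p):
    adj = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(adj, 0)
    return adj
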