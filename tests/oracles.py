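"""Independent brute-force graph-metric implementations.

Deliberately naive (Floyd-Warshall triple loops, exhaustive triangle and
shortest-path enumeration) so they share no code path with the package's
BFS/Brandes kernels. Only meant for graphs with N <= ~12 nodes.
"""

import numpy as np

INF = float("inf")


def floyd_warshall(adj):
    n = len(adj)
    d = [[0.0 if i == j else (1.0 if adj[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def bf_local_clustering(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if adj[nbrs[a]][nbrs[b]]
        )
        out[i] = tri / (k * (k - 1) / 2)
    return out


def bf_mean_clustering(adj):
    return float(bf_local_clustering(adj).mean())


def bf_char_path(adj):
    """Mean shortest-path length over pairs in the largest component."""
    d = floyd_warshall(adj)
    n = len(adj)
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if d[i][j] < INF}
        seen |= comp
        comps.append(sorted(comp))
    comp = max(comps, key=len)
    if len(comp) < 2:
        return float("nan")
    vals = [d[i][j] for ai, i in enumerate(comp) for j in comp[ai + 1:]]
    return float(np.mean(vals))


def bf_global_efficiency(adj):
    d = floyd_warshall(adj)
    n = len(adj)
    s = sum(1.0 / d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < INF)
    return s / (n * (n - 1))


def bf_nodal_efficiency(adj):
    d = floyd_warshall(adj)
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i][j] for j in range(n) if j != i and d[i][j] < INF) / (n - 1)
    return out


def bf_local_efficiency(adj):
    n = len(adj)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        total += bf_global_efficiency(sub)
    return total / n


def _all_shortest_paths(adj, d, s, t):
    """Every shortest s-t path, as node lists (exhaustive recursion)."""
    if s == t:
        return [[t]]
    n = len(adj)
    paths = []
    for v in range(n):
        if adj[v][t] and d[s][v] == d[s][t] - 1:
            for p in _all_shortest_paths(adj, d, s, v):
                paths.append(p + [t])
    return paths


def bf_betweenness(adj):
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    n = len(adj)
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if d[s][t] == INF:
                continue
            paths = _all_shortest_paths(adj, d, s, t)
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def bf_degree(adj):
    return np.array([sum(row) for row in adj], dtype=float)


def bf_assortativity(adj):
    deg = bf_degree(adj)
    xs, ys = [], []
    n = len(adj)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i][j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def random_adjacency(rng, n, p, min_edges=2):
    """Erdos-Renyi adjacency with at least ``min_edges`` edges."""
    while True:
        a = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    a[i, j] = a[j, i] = True
        if a.sum() // 2 >= min_edges:
            return a
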