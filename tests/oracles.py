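"""Independent brute-force oracles for graph metrics and the BH step-up.

Everything here is written against the definitions, using exhaustive
scans (BFS distance tables, triple loops for triangles, geodesic counting
for betweenness) and never calls the implementations under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np

INF = float("inf")


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = adj.shape[0]
    dist = [INF] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == INF:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def distance_matrix(adj: np.ndarray) -> list[list[float]]:
    return [bfs_distances(adj, s) for s in range(adj.shape[0])]


def degree_oracle(adj: np.ndarray) -> list[int]:
    n = adj.shape[0]
    return [sum(int(adj[i, j]) for j in range(n) if j != i) for i in range(n)]


def density_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    e = sum(int(adj[i, j]) for i in range(n) for j in range(i + 1, n))
    return 2.0 * e / (n * (n - 1))


def global_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = distance_matrix(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] != INF:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def clustering_oracle(adj: np.ndarray) -> list[float]:
    n = adj.shape[0]
    out = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(int(adj[a, b]) for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:])
        out.append(links / (k * (k - 1) / 2))
    return out


def local_efficiency_oracle(adj: np.ndarray) -> list[float]:
    n = adj.shape[0]
    out = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out.append(global_efficiency_oracle(sub))
    return out


def _geodesic_counts(adj: np.ndarray, source: int):
    """(distances, number of shortest paths) from source, by BFS."""
    n = adj.shape[0]
    dist = [INF] * n
    sigma = [0] * n
    dist[source] = 0
    sigma[source] = 1
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if not adj[u, v]:
                continue
            if dist[v] == INF:
                dist[v] = dist[u] + 1
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness_oracle(adj: np.ndarray) -> list[float]:
    """Normalized betweenness via pair-by-pair geodesic counting:
    sigma_st(v) = sigma_s(v) * sigma_v(t) when v lies on an s-t geodesic."""
    n = adj.shape[0]
    dist, sigma = zip(*(_geodesic_counts(adj, s) for s in range(n)))
    bc = [0.0] * n
    for s in range(n):
        for t in range(n):
            if t <= s or dist[s][t] == INF:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    norm = (n - 1) * (n - 2) / 2.0
    return [b / norm if norm > 0 else 0.0 for b in bc]


def bh_oracle(pvalues, q: float) -> list[bool]:
    """Literal step-up definition: largest k with p_(k) <= k*q/m, retain all
    p <= p_(k)."""
    p = list(map(float, pvalues))
    m = len(p)
    if m == 0:
        return []
    sorted_p = sorted(p)
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return [False] * m
    cutoff = sorted_p[k_star - 1]
    return [pi <= cutoff for pi in p]


def pearson_oracle(x, y) -> float:
    """Textbook covariance / (sd_x * sd_y) with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / (vx * vy) ** 0.5


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = 1
    return adj
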