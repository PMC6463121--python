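"""Independent brute-force implementations of the graph measures.

These deliberately avoid the package's code paths (scipy csgraph, networkx):
distances come from Floyd-Warshall, shortest-path counts from adjacency
matrix powers (a walk whose length equals the endpoint distance cannot
revisit a vertex, so it is a shortest path), triangles and common-neighbor
sets from explicit enumeration.  Intended for graphs of ~a dozen nodes.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length(adj: np.ndarray) -> tuple[float, int]:
    """(mean finite pair distance, number of disconnected pairs)."""
    d = floyd_warshall(adj)
    vals = [d[i, j] for i, j in itertools.combinations(range(len(adj)), 2)]
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)), len(vals) - len(finite)


def global_efficiency(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    pairs = list(itertools.combinations(range(len(adj)), 2))
    return float(np.mean([1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
                          for i, j in pairs]))


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        neigh = [u for u in range(n) if adj[v, u]]
        if len(neigh) < 2:
            continue
        sub = adj[np.ix_(neigh, neigh)]
        out[v] = global_efficiency(sub)
    return out


def clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        neigh = [u for u in range(n) if adj[v, u]]
        k = len(neigh)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(neigh, 2))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Exact fractional-counting betweenness via matrix-power path counts."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    max_d = int(np.nanmax(np.where(np.isfinite(d), d, 0)))
    powers = [np.eye(n, dtype=np.int64)]
    a = adj.astype(np.int64)
    for _ in range(max_d):
        powers.append(powers[-1] @ a)

    def sigma(s: int, t: int) -> int:
        return int(powers[int(d[s, t])][s, t]) if np.isfinite(d[s, t]) else 0

    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]):
            continue
        total = sigma(s, t)
        for v in range(n):
            if v in (s, t):
                continue
            if np.isfinite(d[s, v]) and np.isfinite(d[v, t]) \
                    and d[s, v] + d[v, t] == d[s, t]:
                out[v] += sigma(s, v) * sigma(v, t) / total
    return out


def cn_lcl(adj: np.ndarray) -> tuple[list[int], list[int]]:
    """CN and LCL vectors over existing edges with CN > 0, in edge order."""
    n = adj.shape[0]
    cns, lcls = [], []
    for u, v in itertools.combinations(range(n), 2):
        if not adj[u, v]:
            continue
        common = [w for w in range(n) if adj[u, w] and adj[v, w]]
        if not common:
            continue
        lcl = sum(adj[a, b] for a, b in itertools.combinations(common, 2))
        cns.append(len(common))
        lcls.append(int(lcl))
    return cns, lcls


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def lcp_corr(adj: np.ndarray) -> float:
    cns, lcls = cn_lcl(adj)
    if len(cns) < 2 or np.std(cns) == 0 or np.std(lcls) == 0:
        return float("nan")
    return pearson(cns, lcls)


def modularity_of_partition(adj: np.ndarray, partition) -> float:
    """Newman modularity of a given node partition, from the definition."""
    m2 = adj.sum()  # 2m
    deg = adj.sum(axis=0)
    q = 0.0
    for comm in partition:
        for i in comm:
            for j in comm:
                q += adj[i, j] - deg[i] * deg[j] / m2
    return float(q / m2)


def bh_adjusted(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by direct step-up search."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted
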