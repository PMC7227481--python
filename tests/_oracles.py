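"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different routes from the library code: betweenness
through the path-count product identity (not Brandes' accumulation),
closeness through explicit BFS distance sums, eigenvector centrality through
a dense symmetric eigendecomposition, NC/LAC through per-edge common-neighbour
counting, the hypergeometric tail through a binomial-coefficient sum, and BH
through the naive min-over-suffix definition.
"""

from __future__ import annotations

from collections import deque
from math import comb

import networkx as nx
import numpy as np


def bfs_dist_and_counts(g: nx.Graph, s):
    """(distances, shortest-path counts) from source s; unreachable = -1/0."""
    dist = {v: -1 for v in g}
    sigma = {v: 0 for v in g}
    dist[s], sigma[s] = 0, 1
    q = deque([s])
    while q:
        v = q.popleft()
        for w in g[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def betweenness_oracle(g: nx.Graph) -> dict:
    """BC via sigma_st(v) = sigma_sv * sigma_vt when d(s,v)+d(v,t) = d(s,t);
    each unordered pair counted once."""
    nodes = list(g)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_dist_and_counts(g, s)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if dist[s][t] <= 0:
                continue  # same node or different components
            for v in nodes:
                if v == s or v == t:
                    continue
                if dist[s][v] >= 0 and dist[v][t] >= 0 and dist[s][v] + dist[v][t] == dist[s][t]:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def closeness_oracle(g: nx.Graph) -> dict:
    cc = {}
    for v in g:
        dist, _ = bfs_dist_and_counts(g, v)
        reach = [d for d in dist.values() if d > 0]
        cc[v] = len(reach) / sum(reach) if reach else 0.0
    return cc


def eigenvector_oracle(g: nx.Graph) -> dict:
    """Principal eigenvector by dense eigendecomposition, max-entry = 1.

    Only meaningful when the top eigenvalue is simple (e.g. connected
    graphs); callers should pass connected graphs.
    """
    nodes = sorted(g)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    vec = np.abs(vec)  # Perron vector is signable to non-negative
    vec = vec / vec.max()
    return dict(zip(nodes, vec))


def ecc_oracle(g: nx.Graph, u, v) -> float:
    denom = min(g.degree[u] - 1, g.degree[v] - 1)
    if denom <= 0:
        return 0.0
    return len(list(nx.common_neighbors(g, u, v))) / denom


def nc_oracle(g: nx.Graph) -> dict:
    return {v: sum(ecc_oracle(g, v, u) for u in g[v]) for v in g}


def lac_oracle(g: nx.Graph) -> dict:
    """LAC via triangle counts: 2 * triangles(v) / deg(v)."""
    tri = nx.triangles(g)
    return {v: (2.0 * tri[v] / g.degree[v] if g.degree[v] else 0.0) for v in g}


def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) as an explicit sum of counting ratios."""
    hi = min(K, n)
    if k <= 0:
        return 1.0
    if k > hi:
        return 0.0
    total = comb(N, n)
    favourable = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1))
    return favourable / total


def bh_oracle(pvals):
    """Benjamini–Hochberg by the naive min-over-suffix definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, pvals[i] * m / (rank + 1))
        adj[i] = min(1.0, running_min)
    return adj


def connected_er(n: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi graph conditioned on connectivity (resample until)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n > 0 and nx.is_connected(g):
            return g
    raise RuntimeError(f"no connected G({n},{p}) after 200 draws")
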