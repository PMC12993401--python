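"""Compiled kernels for the graph operations that dominate run time.

Everything here works on dense boolean adjacency matrices (the networks are
small, a few hundred nodes, but are visited tens of thousands of times in
replicate simulations). Distances use breadth-first search because all graphs
are binary.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = [
    "all_pairs_bfs",
    "local_efficiency_per_node",
    "rewire_inplace",
    "greedy_merge_labels",
]


@numba.njit(cache=True)
def all_pairs_bfs(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of a binary graph; -1 marks unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@numba.njit(cache=True)
def _subgraph_efficiency(adj: np.ndarray, nodes: np.ndarray) -> float:
    """Global efficiency of the subgraph induced by ``nodes`` (ordered pairs)."""
    k = nodes.shape[0]
    if k < 2:
        return 0.0
    sub = np.empty((k, k), dtype=np.bool_)
    for i in range(k):
        for j in range(k):
            sub[i, j] = adj[nodes[i], nodes[j]]
    dist = all_pairs_bfs(sub)
    total = 0.0
    for i in range(k):
        for j in range(k):
            if i != j and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (k * (k - 1))


@numba.njit(cache=True)
def local_efficiency_per_node(adj: np.ndarray) -> np.ndarray:
    """Per-node local efficiency: global efficiency of each neighbourhood."""
    n = adj.shape[0]
    out = np.zeros(n, dtype=np.float64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                k += 1
        if k < 2:
            continue
        nbrs = np.empty(k, dtype=np.int64)
        c = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[c] = j
                c += 1
        out[i] = _subgraph_efficiency(adj, nbrs)
    return out


@numba.njit(cache=True)
def rewire_inplace(adj: np.ndarray, edges: np.ndarray, n_attempts: int, seed: int) -> int:
    """Degree-preserving double-edge swaps applied in place.

    ``edges`` is an (m, 2) int array matching ``adj``; both are updated.
    Swaps touching fewer than four distinct nodes, or that would create a
    multi-edge, are rejected. Returns the number of accepted swaps.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


@numba.njit(cache=True)
def greedy_merge_labels(adj: np.ndarray) -> np.ndarray:
    """Agglomerative greedy modularity maximization (CNM-style).

    Starts from singletons and repeatedly merges the community pair with the
    largest positive modularity gain; ties break to the lexicographically
    smallest community index pair. Returns raw root labels (not compacted).
    """
    n = adj.shape[0]
    parent = np.arange(n)
    deg = np.zeros(n, dtype=np.float64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                deg[i] += 1.0
    m2 = deg.sum()
    if m2 == 0.0:
        return parent
    e = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                e[i, j] = 1.0 / m2
    a = deg / m2
    active = np.ones(n, dtype=np.bool_)
    while True:
        best = 0.0
        bi = -1
        bj = -1
        for i in range(n):
            if not active[i]:
                continue
            for j in range(i + 1, n):
                if not active[j]:
                    continue
                dq = 2.0 * (e[i, j] - a[i] * a[j])
                if dq > best:
                    best = dq
                    bi = i
                    bj = j
        if bi < 0:
            break
        # merge bj into bi; e[bi,bi] becomes e_ii + e_jj + 2 e_ij
        eij = e[bi, bj]
        for k in range(n):
            if active[k] and k != bi and k != bj:
                e[bi, k] += e[bj, k]
                e[k, bi] += e[k, bj]
        e[bi, bi] += e[bj, bj] + 2.0 * eij
        a[bi] += a[bj]
        active[bj] = False
        parent[bj] = bi
    # resolve chains to roots
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        r = i
        while parent[r] != r:
            r = parent[r]
        labels[i] = r
    return labels
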