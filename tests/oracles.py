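"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive (enumeration, direct definitions,
exhaustive search) and shares no code with the package under test.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def clustering_oracle(g: nx.Graph) -> dict:
    """Per-node clustering by explicit triangle enumeration."""
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def _bfs_dist(g: nx.Graph, source) -> dict:
    return nx.single_source_shortest_path_length(g, source)


def path_length_oracle(g: nx.Graph) -> tuple[float, bool]:
    """Mean finite shortest-path length over ordered pairs; connectivity flag."""
    dists = []
    n = g.number_of_nodes()
    reachable_pairs = 0
    for s in g.nodes:
        d = _bfs_dist(g, s)
        for t, dv in d.items():
            if t != s:
                dists.append(dv)
                reachable_pairs += 1
    if not dists:
        return float("nan"), False
    return float(np.mean(dists)), reachable_pairs == n * (n - 1)

def global_efficiency_oracle(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for s in g.nodes:
        d = _bfs_dist(g, s)
        for t, dv in d.items():
            if t != s:
                total += 1.0 / dv
    return total / (n * (n - 1))


def nodal_efficiency_oracle(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    out = {}
    for s in g.nodes:
        d = _bfs_dist(g, s)
        out[s] = sum(1.0 / dv for t, dv in d.items() if t != s) / (n - 1)
    return out


def local_efficiency_oracle(g: nx.Graph) -> float:
    vals = []
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if len(nbrs) < 2:
            vals.append(0.0)
        else:
            vals.append(global_efficiency_oracle(g.subgraph(nbrs)))
    return float(np.mean(vals))


def betweenness_oracle(g: nx.Graph) -> dict:
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    n = g.number_of_nodes()
    acc = {v: 0.0 for v in g.nodes}
    if n < 3:
        return acc
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                acc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: acc[v] / norm for v in acc}


def modularity_oracle(adj: np.ndarray, labels: np.ndarray) -> float:
    """Definitional double sum: sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j) / 2m."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1)
    m2 = a.sum()
    if m2 == 0:
        return 0.0
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


def set_partitions(items: list):
    """All partitions of a list (recursive generator)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_partition_oracle(adj: np.ndarray) -> tuple[float, list]:
    """Exhaustive-search maximum-modularity partition (tiny graphs only)."""
    n = adj.shape[0]
    best_q, best_p = -np.inf, None
    for p in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(p):
            labels[block] = ci
        q = modularity_oracle(adj, labels)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


def module_counts_oracle(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Edge-by-edge tally of within/between-module edge counts."""
    k = int(labels.max()) + 1
    counts = np.zeros((k, k), dtype=int)
    n = adj.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                a, b = sorted((labels[i], labels[j]))
                counts[a, b] += 1
    return counts + np.triu(counts, k=1).T


def participation_oracle(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Direct per-node summation of 1 - sum_m (k_im/k_i)^2."""
    n = adj.shape[0]
    k = int(labels.max()) + 1
    out = np.zeros(n)
    for i in range(n):
        ki = adj[i].sum()
        if ki == 0:
            continue
        s = 0.0
        for m in range(k):
            kim = adj[i][labels == m].sum()
            s += (kim / ki) ** 2
        out[i] = 1.0 - s
    return out


def wilcoxon_exact_oracle(diffs: np.ndarray, tail: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments.

    Zeros must already be removed; no tied absolute values allowed.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_pos = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(ranks[np.array(signs, dtype=bool)].sum())
    stats = np.array(stats)
    if tail == "greater":
        # more positive mass than observed
        return float(np.mean(stats >= w_pos))
    if tail == "less":
        return float(np.mean(stats <= w_pos))
    p = 2.0 * min(np.mean(stats >= w_pos), np.mean(stats <= w_pos))
    return float(min(p, 1.0))


def bh_oracle(pvals: list[float]) -> list[float]:
    """Step-up BH applied literally: sort, q_i = p_i * m / i, cummin from top."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = pvals[i] * m / (rank_from_top + 1)
        prev = min(prev, val)
        q[i] = prev
    return [min(v, 1.0) for v in q]


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of midranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def nx_to_adj(g: nx.Graph) -> np.ndarray:
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n), dtype=bool)
    for u, v in g.edges:
        a[idx[u], idx[v]] = True
        a[idx[v], idx[u]] = True
    return a


def small_connected_graphs(max_nodes: int = 6):
    """Every connected simple graph with 3..max_nodes nodes (graph atlas)."""
    for g in nx.graph_atlas_g()[1:]:
        n = g.number_of_nodes()
        if 3 <= n <= max_nodes and nx.is_connected(g):
            yield g


def random_graphs(n_graphs: int, max_nodes: int, seed: int):
    """Random Erdos-Renyi graphs (possibly disconnected) up to max_nodes."""
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(4, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.75))
        yield nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
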