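"""Binary graph metrics: global (Cp, Lp, Eg, Eloc, Q and the small-world
ratios) and nodal (degree, nodal efficiency, betweenness), with AUC summaries
over the sparsity grid.

All functions take a dense boolean adjacency matrix of a simple undirected
graph. Path-based quantities average over *ordered* node pairs; unreachable
pairs contribute 0 to efficiencies and are excluded from the characteristic
path length (which is flagged when the graph is disconnected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from ._fast import all_pairs_bfs, local_efficiency_per_node
from .connectivity import AdjacencyStack
from .nulls import NullConfig, small_world_normalize

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eg", "Eloc", "gamma", "lambda", "sigma", "Q")
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


def _check_simple(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(adj)):
        raise ValueError("self-loops are not allowed")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    return adj


def degrees(adj: np.ndarray) -> np.ndarray:
    return _check_simple(adj).sum(axis=1).astype(int)


def clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    """Watts-Strogatz binary clustering per node: 2*T_i / (k_i (k_i - 1))."""
    adj = _check_simple(adj)
    a = adj.astype(float)
    triangles = np.diag(a @ a @ a) / 2.0
    k = a.sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def average_clustering(adj: np.ndarray) -> float:
    return float(clustering_coefficients(adj).mean())


def distance_matrix(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths; np.inf marks unreachable pairs."""
    adj = _check_simple(adj)
    d = all_pairs_bfs(np.ascontiguousarray(adj)).astype(float)
    d[d < 0] = np.inf
    return d


def characteristic_path_length(adj: np.ndarray) -> tuple[float, bool]:
    """(Lp, connected). Mean finite shortest-path length over ordered pairs.

    Unreachable pairs are excluded; ``connected`` is False when any exist.
    Lp is NaN when no finite pair exists (edgeless graph).
    """
    d = distance_matrix(adj)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    connected = bool(finite.sum() == n * (n - 1))
    if not finite.any():
        return float("nan"), False
    return float(d[finite].mean()), connected


def global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d over ordered pairs, unreachable pairs contributing 0."""
    d = distance_matrix(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per node: mean of 1/d to every other node (0 for unreachable)."""
    d = distance_matrix(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbourhood subgraph."""
    adj = _check_simple(adj)
    return float(local_efficiency_per_node(np.ascontiguousarray(adj)).mean())


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness centrality (fraction of shortest paths).

    Computed with igraph's Brandes implementation, divided by (N-1)(N-2)/2.
    """
    adj = _check_simple(adj)
    n = adj.shape[0]
    if n < 3:
        return np.zeros(n)
    r, c = np.nonzero(np.triu(adj, k=1))
    g = ig.Graph(n=n, edges=list(zip(r.tolist(), c.tolist())))
    raw = np.asarray(g.betweenness(), dtype=float)
    return raw / ((n - 1) * (n - 2) / 2.0)


def auc(values: np.ndarray, densities: np.ndarray) -> float:
    """Trapezoidal area under a metric-vs-density curve."""
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if values.shape != densities.shape or len(values) < 2:
        raise ValueError("curve and grid must have equal length >= 2")
    if np.any(np.isnan(values)):
        warnings.warn("NaN in metric curve; AUC is NaN")
    return float(np.trapezoid(values, densities))


@dataclass(frozen=True)
class GlobalMetrics:
    """Global metrics of one adjacency slice."""

    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    gamma: float
    lam: float
    sigma: float
    Q: float
    connected: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.Cp,
            "Lp": self.Lp,
            "Eg": self.Eg,
            "Eloc": self.Eloc,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "Q": self.Q,
        }


def global_metrics(adj: np.ndarray, null_config: NullConfig, seed: int) -> GlobalMetrics:
    """All global metrics of one slice, with the null-normalized ratios."""
    from .modules import detect_communities  # local import avoids a cycle

    adj = _check_simple(adj)
    cp = average_clustering(adj)
    # one BFS serves both path length and global efficiency
    d = distance_matrix(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    connected = bool(finite.sum() == n * (n - 1))
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    eg = float(inv.sum() / (n * (n - 1)))
    eloc = local_efficiency(adj)
    gamma, lam, sigma = small_world_normalize(adj, cp, lp, null_config, seed)
    q = detect_communities(adj).Q
    return GlobalMetrics(cp, lp, eg, eloc, gamma, lam, sigma, q, connected)


@dataclass(frozen=True)
class MetricCurves:
    """Metric values as functions of density for one subject-session."""

    subject_id: str
    session: str
    densities: np.ndarray
    global_table: pd.DataFrame  # rows = densities, columns = GLOBAL_METRIC_NAMES
    nodal: dict[str, np.ndarray]  # metric -> (n_densities, n_rois)

    def global_auc(self) -> dict[str, float]:
        return {
            m: auc(self.global_table[m].to_numpy(), self.densities)
            for m in self.global_table.columns
        }

    def nodal_auc(self) -> dict[str, np.ndarray]:
        return {
            m: np.array(
                [auc(curve[:, i], self.densities) for i in range(curve.shape[1])]
            )
            for m, curve in self.nodal.items()
        }


def slice_seed(master_seed: int, subject_idx: int, session_idx: int, density_idx: int) -> int:
    """Deterministic per-slice seed below 2**31 for the null ensemble."""
    ss = np.random.SeedSequence([master_seed, subject_idx, session_idx, density_idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def compute_curves(
    stack: AdjacencyStack,
    null_config: NullConfig,
    master_seed: int,
    subject_idx: int = 0,
    session_idx: int = 0,
    include_nodal: bool = True,
) -> MetricCurves:
    """Global (and optionally nodal) metric curves across the sparsity grid.

    Each slice's null ensemble is seeded deterministically from
    (master seed, subject, session, density) so reruns reproduce exactly.
    """
    dens = stack.grid.values
    glob_rows = []
    nodal = (
        {m: np.zeros((len(dens), stack.n_rois)) for m in NODAL_METRIC_NAMES}
        if include_nodal
        else {}
    )
    for k, (_, adj) in enumerate(stack):
        seed = slice_seed(master_seed, subject_idx, session_idx, k)
        gm = global_metrics(adj, null_config, seed)
        glob_rows.append(gm.as_dict())
        if include_nodal:
            nodal["degree"][k] = degrees(adj)
            nodal["nodal_efficiency"][k] = nodal_efficiency(adj)
            nodal["betweenness"][k] = betweenness(adj)
    table = pd.DataFrame(glob_rows, index=dens)[list(GLOBAL_METRIC_NAMES)]
    return MetricCurves(stack.subject_id, stack.session, dens, table, nodal)
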