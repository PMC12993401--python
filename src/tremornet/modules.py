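"""Group-level community structure and module-resolved connectivity accounting.

The group graph is the element-wise mean of the baseline Fisher-z matrices
binarized at a single density (default 0.15). Communities are found by a
deterministic agglomerative greedy modularity optimizer (CNM-style: start from
singletons, repeatedly merge the community pair with the largest positive
modularity gain, ties broken toward the smallest community indices). The
partition is estimated once from baseline and held fixed for both sessions;
per-subject binary edge counts within and between modules, the participation
coefficient, and module-restricted nodal statistics are all computed against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._fast import greedy_merge_labels
from .connectivity import ConnectivityMatrix, SparsityGrid, binarize_stack, group_mean_fc

#: Q at or above this is conventionally taken as non-random community structure.
NONRANDOM_Q = 0.3


@dataclass(frozen=True)
class ModularPartition:
    """A node->module assignment with its modularity on the source graph."""

    assignment: np.ndarray
    Q: float

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if len(self.assignment) else 0

    @property
    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_modules)

    @property
    def nonrandom(self) -> bool:
        return self.Q >= NONRANDOM_Q

    def nodes_of(self, modules: set[int] | list[int]) -> np.ndarray:
        return np.flatnonzero(np.isin(self.assignment, list(modules)))

    def to_tsv(self, path: str | Path, labels: tuple[str, ...] | None = None) -> None:
        n = len(self.assignment)
        df = pd.DataFrame(
            {
                "roi_label": labels if labels is not None else [str(i) for i in range(n)],
                "module": self.assignment,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def modularity_Q(adj: np.ndarray, assignment: np.ndarray) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) of a partition on a binary graph."""
    adj = np.asarray(adj, dtype=float)
    assignment = np.asarray(assignment)
    if len(assignment) != adj.shape[0]:
        raise ValueError("assignment must cover all nodes")
    m2 = adj.sum()
    if m2 == 0:
        return 0.0
    k = int(assignment.max()) + 1
    z = np.zeros((adj.shape[0], k))
    z[np.arange(adj.shape[0]), assignment] = 1.0
    block = z.T @ adj @ z / m2
    e_cc = np.diag(block)
    a_c = block.sum(axis=1)
    return float(np.sum(e_cc - a_c**2))


def _compact_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel to consecutive integers in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen)
        out[i] = seen[r]
    return out


def detect_communities(adj: np.ndarray) -> ModularPartition:
    """Greedy agglomerative modularity maximization (deterministic).

    On an edgeless graph every node is its own module with Q = 0.
    """
    adj = np.ascontiguousarray(np.asarray(adj, dtype=bool))
    if adj.shape[0] == 0:
        raise ValueError("graph is empty")
    labels = _compact_labels(greedy_merge_labels(adj))
    return ModularPartition(labels, modularity_Q(adj, labels))


def group_graph(
    baseline_fcs: list[ConnectivityMatrix], density: float = 0.15
) -> tuple[np.ndarray, ConnectivityMatrix]:
    """Mean baseline FC binarized at one density: (adjacency, mean FC)."""
    mean_fc = group_mean_fc(baseline_fcs)
    grid = SparsityGrid(start=density, stop=min(2 * density, 1.0), step=density)
    stack = binarize_stack(mean_fc, grid)
    return stack.adjacency(0), mean_fc


@dataclass(frozen=True)
class ModuleEdgeCounts:
    """K x K symmetric matrix of binary edge counts for one subject-session.

    Diagonal entries are within-module edges, off-diagonal entries edges with
    one endpoint in each module.
    """

    counts: np.ndarray
    subject_id: str
    session: str

    @property
    def total_edges(self) -> int:
        c = self.counts
        return int(np.diag(c).sum() + np.triu(c, k=1).sum())


def module_edge_counts(
    adj: np.ndarray, partition: ModularPartition, subject_id: str = "", session: str = ""
) -> ModuleEdgeCounts:
    """Count edges within and between modules on one binary slice."""
    adj = np.asarray(adj, dtype=float)
    assignment = partition.assignment
    if len(assignment) != adj.shape[0]:
        raise ValueError("partition and graph size mismatch")
    k = partition.n_modules
    z = np.zeros((adj.shape[0], k))
    z[np.arange(adj.shape[0]), assignment] = 1.0
    block = z.T @ adj @ z
    counts = np.triu(block, k=1) + np.triu(block, k=1).T
    np.fill_diagonal(counts, np.diag(block) / 2.0)
    return ModuleEdgeCounts(counts.astype(int), subject_id, session)


def participation(adj: np.ndarray, partition: ModularPartition) -> np.ndarray:
    """Participation coefficient per node: 1 - sum_m (k_im / k_i)^2.

    Isolated nodes score 0; a node with all edges in one module scores 0; the
    upper bound is 1 - 1/K.
    """
    adj = np.asarray(adj, dtype=float)
    assignment = partition.assignment
    k_total = adj.sum(axis=1)
    kmat = np.zeros((adj.shape[0], partition.n_modules))
    for m in range(partition.n_modules):
        kmat[:, m] = adj[:, assignment == m].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(k_total[:, None] > 0, kmat / k_total[:, None], 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    p[k_total == 0] = 0.0
    return p


def restricted_nodal_table(
    nodal_auc: pd.DataFrame,
    participation_table: pd.DataFrame,
    partition: ModularPartition,
    implicated_modules: set[int],
    labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Nodal table restricted to the nodes of the implicated modules.

    ``nodal_auc`` is tidy (subject, session, node, metric, value) with
    AUC-over-grid nodal metrics; ``participation_table`` the same shape with the
    participation coefficient at the modular density. Returns their
    concatenation filtered to the union of the implicated modules' nodes
    (empty, with the same columns, when no module is implicated).
    """
    combined = pd.concat([nodal_auc, participation_table], ignore_index=True)
    if not implicated_modules:
        return combined.iloc[0:0]
    nodes = set(partition.nodes_of(implicated_modules).tolist())
    out = combined[combined["node"].isin(nodes)].reset_index(drop=True)
    if labels is not None:
        out = out.assign(roi_label=[labels[i] for i in out["node"]])
    return out
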