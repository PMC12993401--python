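"""Degree-preserving random reference networks and small-world normalization.

The null model is the Maslov-Sneppen double-edge swap: repeated swaps of edge
pairs that preserve every node's degree while randomizing the topology. The
normalized clustering coefficient gamma, normalized path length lambda and
small-worldness sigma = gamma/lambda compare a graph's Cp and Lp with the
ensemble means of its rewired references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._fast import rewire_inplace


@dataclass(frozen=True)
class NullConfig:
    """Null-ensemble settings: ensemble size and attempted swaps per edge."""

    n_nulls: int = 100
    swaps_per_edge: int = 10

    def __post_init__(self) -> None:
        if self.n_nulls < 1 or self.swaps_per_edge < 0:
            raise ValueError("invalid null-ensemble configuration")


def rewire(adj: np.ndarray, swaps_per_edge: int = 10, seed: int = 0) -> np.ndarray:
    """Return a degree-preserving randomized copy of a simple binary graph.

    Attempts ``swaps_per_edge * m`` double-edge swaps; swaps that would create
    a self-loop or multi-edge are rejected, so the result is always simple with
    the original degree sequence. Deterministic given ``seed``. Graphs with
    fewer than 2 edges are returned unchanged with a warning.
    """
    adj = np.asarray(adj, dtype=bool)
    r, c = np.nonzero(np.triu(adj, k=1))
    m = len(r)
    out = adj.copy()
    if m < 2:
        warnings.warn("graph has fewer than 2 edges; returning a copy")
        return out
    edges = np.stack([r, c], axis=1).astype(np.int64)
    rewire_inplace(out, edges, int(swaps_per_edge * m), int(seed) % (2**32))
    return out


def null_reference_means(
    adj: np.ndarray, config: NullConfig, seed: int
) -> tuple[float, float]:
    """Ensemble means of (Cp, Lp) over rewired null networks.

    Null path lengths use the same finite-pairs convention as the real graph.
    """
    from .metrics import average_clustering, characteristic_path_length

    cps, lps = [], []
    for i in range(config.n_nulls):
        null = rewire(adj, config.swaps_per_edge, seed=(seed + i) % (2**31))
        cps.append(average_clustering(null))
        lp, _ = characteristic_path_length(null)
        lps.append(lp)
    return float(np.mean(cps)), float(np.nanmean(lps))


def small_world_normalize(
    adj: np.ndarray,
    cp: float,
    lp: float,
    config: NullConfig,
    seed: int,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of a graph against its rewired null ensemble.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda.
    gamma is NaN (with a warning) when the null ensemble has zero mean
    clustering, which happens only at extreme sparsity.
    """
    null_cp, null_lp = null_reference_means(adj, config, seed)
    if null_cp == 0.0:
        warnings.warn("null ensemble mean clustering is 0; gamma undefined")
        gamma = float("nan")
    else:
        gamma = cp / null_cp
    lam = lp / null_lp if null_lp and np.isfinite(null_lp) else float("nan")
    sigma = gamma / lam
    return gamma, lam, sigma


def audit_degree_preservation(original: np.ndarray, null: np.ndarray) -> bool:
    """True when the null is simple with the original's exact degree sequence."""
    null = np.asarray(null, dtype=bool)
    if np.any(np.diag(null)) or not np.array_equal(null, null.T):
        return False
    return np.array_equal(original.sum(axis=1), null.sum(axis=1))
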