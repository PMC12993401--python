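"""Replicate-cohort simulation experiments.

Two calibration experiments run the pipeline on many independently seeded
synthetic cohorts:

* :func:`type_one_error` — cohorts with every planted effect removed, to
  estimate the empirical size of the one-tailed global AUC family (each
  metric's paired test should reject at about the nominal rate).
* :func:`effect_recovery` — cohorts with the planted follow-up effect, to
  estimate how often the pipeline flags the planted module pairs as
  trend-level changes and ranks a planted hub top of the module-restricted
  betweenness family.

Replicates use deliberately scaled-down settings (coarse density grid, small
null ensembles) so hundreds of cohorts run in desk minutes; the settings are
arguments, not constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import BASELINE, CohortDesign, simulate_cohort
from .connectivity import SparsityGrid, binarize_stack, fc_matrix
from .metrics import auc, betweenness, compute_curves, degrees, nodal_efficiency
from .modules import detect_communities, group_graph, module_edge_counts, participation
from .nulls import NullConfig
from .stats import GLOBAL_DIRECTIONS, global_family_tests, run_statistical_plan

#: Coarse grid used by replicate experiments that need the null-normalized
#: global metrics (4 densities keeps 200 cohorts within desk minutes).
TYPE_ONE_GRID = SparsityGrid(0.10, 0.40, 0.10)
#: Coarse grid for nodal-AUC recovery replicates; contains the modular density.
RECOVERY_GRID = SparsityGrid(0.10, 0.40, 0.05)
#: Small null ensemble for replicate runs.
REPLICATE_NULLS = NullConfig(n_nulls=3, swaps_per_edge=5)


def _global_auc_table(
    sessions, grid: SparsityGrid, nulls: NullConfig, master_seed: int
) -> pd.DataFrame:
    subjects = sorted({s.subject_id for s in sessions})
    rows = []
    for ss in sessions:
        stack = binarize_stack(fc_matrix(ss), grid)
        curves = compute_curves(
            stack,
            nulls,
            master_seed,
            subject_idx=subjects.index(ss.subject_id),
            session_idx=0 if ss.session == BASELINE else 1,
            include_nodal=False,
        )
        for metric, value in curves.global_auc().items():
            rows.append((ss.subject_id, ss.session, metric, value))
    return pd.DataFrame(rows, columns=["subject", "session", "metric", "auc"])


def type_one_error(
    n_replicates: int = 200,
    seed: int = 0,
    design: CohortDesign | None = None,
    grid: SparsityGrid = TYPE_ONE_GRID,
    nulls: NullConfig = REPLICATE_NULLS,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Empirical size of the one-tailed global family on null cohorts.

    Returns (pooled rejection fraction, per-metric table). The design defaults
    to the scaled study design with all planted effects removed; each replicate
    gets an independent sub-seed.
    """
    base = (design or CohortDesign.scaled()).null()
    ss = np.random.SeedSequence(seed)
    rejections = {m: 0 for m in GLOBAL_DIRECTIONS}
    tested = {m: 0 for m in GLOBAL_DIRECTIONS}
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        d = replace(base, seed=rep_seed)
        sessions = simulate_cohort(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = _global_auc_table(sessions, grid, nulls, rep_seed)
            tests = global_family_tests(table, alpha=alpha)
        for row in tests.itertuples(index=False):
            if np.isfinite(row.p_raw):
                tested[row.metric] += 1
                rejections[row.metric] += int(row.p_raw < alpha)
    per_metric = pd.DataFrame(
        {
            "metric": list(GLOBAL_DIRECTIONS),
            "n": [tested[m] for m in GLOBAL_DIRECTIONS],
            "rejection_rate": [
                rejections[m] / tested[m] if tested[m] else np.nan
                for m in GLOBAL_DIRECTIONS
            ],
        }
    )
    pooled = sum(rejections.values()) / max(sum(tested.values()), 1)
    return pooled, per_metric


def match_modules(detected: np.ndarray, planted: np.ndarray) -> dict[int, int]:
    """Map each detected module to the planted module it overlaps most."""
    detected = np.asarray(detected)
    planted = np.asarray(planted)
    mapping = {}
    for d in np.unique(detected):
        members = planted[detected == d]
        mapping[int(d)] = int(np.bincount(members).argmax())
    return mapping


@dataclass(frozen=True)
class RecoveryOutcome:
    """Per-replicate recovery flags."""

    pairs_flagged: bool  # both planted pairs trend-flagged
    pairs_rank_first: bool  # planted pairs have the smallest between-module p-values
    hub_top: bool  # largest restricted betweenness increase is a planted hub


def recovery_replicate(
    design: CohortDesign,
    grid: SparsityGrid = RECOVERY_GRID,
    modular_density: float = 0.15,
) -> RecoveryOutcome:
    """Run one planted-effect cohort through connectivity, modules and stats.

    The null-normalized global metrics are not needed for recovery, so this
    replicate skips null ensembles entirely (nodal AUC + module counts only).
    """
    sessions = simulate_cohort(design)
    stacks = {
        (ss.subject_id, ss.session): binarize_stack(fc_matrix(ss), grid)
        for ss in sessions
    }
    baseline_fcs = [fc_matrix(ss) for ss in sessions if ss.session == BASELINE]
    adj, _ = group_graph(baseline_fcs, modular_density)
    part = detect_communities(adj)

    nodal_rows, count_rows, part_rows = [], [], []
    dens = grid.values
    for (sid, sess), stack in stacks.items():
        curves = {
            "degree": np.zeros((len(dens), stack.n_rois)),
            "nodal_efficiency": np.zeros((len(dens), stack.n_rois)),
            "betweenness": np.zeros((len(dens), stack.n_rois)),
        }
        for k, (_, a) in enumerate(stack):
            curves["degree"][k] = degrees(a)
            curves["nodal_efficiency"][k] = nodal_efficiency(a)
            curves["betweenness"][k] = betweenness(a)
        for metric, c in curves.items():
            for node in range(stack.n_rois):
                nodal_rows.append((sid, sess, node, metric, auc(c[:, node], dens)))
        slice_adj = stack.adjacency_at_density(modular_density)
        counts = module_edge_counts(slice_adj, part, sid, sess)
        for a_ in range(part.n_modules):
            for b_ in range(a_, part.n_modules):
                count_rows.append((sid, sess, a_, b_, int(counts.counts[a_, b_])))
        for node, v in enumerate(participation(slice_adj, part)):
            part_rows.append((sid, sess, node, "participation", v))

    nodal_auc = pd.DataFrame(
        nodal_rows, columns=["subject", "session", "node", "metric", "auc"]
    )
    module_counts = pd.DataFrame(
        count_rows, columns=["subject", "session", "module_a", "module_b", "count"]
    )
    part_table = pd.DataFrame(
        part_rows, columns=["subject", "session", "node", "metric", "auc"]
    )
    empty_global = pd.DataFrame(columns=["subject", "session", "metric", "auc"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_statistical_plan(
            empty_global, nodal_auc, module_counts, part_table, part
        )

    mapping = match_modules(part.assignment, np.asarray(design.planted_partition))
    planted_pairs = {tuple(sorted(p)) for p in design.effect_pairs}
    inter = report.inter_module_tests
    mapped_pairs = [
        tuple(sorted((mapping[int(r.module_a)], mapping[int(r.module_b)])))
        for r in inter.itertuples(index=False)
    ]
    flagged = {mp for mp, t in zip(mapped_pairs, inter["trend"]) if t}
    pairs_flagged = planted_pairs <= flagged
    order = np.argsort(inter["p_raw"].to_numpy(), kind="stable")
    top_pairs = {mapped_pairs[i] for i in order[: len(planted_pairs)]}
    pairs_rank_first = top_pairs == planted_pairs

    rt = report.restricted_tests
    bc = rt[rt["metric"] == "betweenness"]
    if bc.empty:
        hub_top = False
    else:
        delta = (bc["mean_followup"] - bc["mean_baseline"]).to_numpy()
        hub_top = int(bc["node"].to_numpy()[np.argmax(delta)]) in set(design.hub_rois)
    return RecoveryOutcome(pairs_flagged, pairs_rank_first, hub_top)


def effect_recovery(
    n_replicates: int = 50,
    seed: int = 0,
    design: CohortDesign | None = None,
    grid: SparsityGrid = RECOVERY_GRID,
    modular_density: float = 0.15,
) -> pd.DataFrame:
    """Recovery rates of the planted follow-up effect over replicate cohorts.

    Returns a one-row table with the fraction of replicates in which (a) both
    planted module pairs were trend-flagged, (b) they ranked first by paired
    evidence, and (c) the top restricted betweenness increase was a planted hub.
    """
    base = design or CohortDesign.scaled()
    ss = np.random.SeedSequence(seed)
    outcomes = []
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        d = replace(base, seed=rep_seed)
        outcomes.append(recovery_replicate(d, grid, modular_density))
    return pd.DataFrame(
        {
            "n_replicates": [n_replicates],
            "pairs_flagged_rate": [np.mean([o.pairs_flagged for o in outcomes])],
            "pairs_rank_first_rate": [np.mean([o.pairs_rank_first for o in outcomes])],
            "hub_top_rate": [np.mean([o.hub_top for o in outcomes])],
        }
    )
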