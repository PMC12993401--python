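"""Paired longitudinal statistics: normality-gated paired tests, one-tailed
global comparisons, Benjamini-Hochberg FDR families, and Spearman clinical
correlations.

The test for each paired sample is chosen by a Shapiro-Wilk gate on the paired
differences (p >= 0.05 -> paired t-test, else Wilcoxon signed-rank). Global
metrics are tested one-tailed with directions fixed a priori (small-worldness,
normalized clustering, clustering, efficiencies expected to increase; path
lengths and modularity expected to decrease) and left uncorrected; nodal and
modular families are tested two-tailed with BH-FDR within each family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .modules import ModularPartition, restricted_nodal_table

#: A priori one-tailed directions for the global AUC family ("greater" means
#: the follow-up value is hypothesized to exceed baseline).
GLOBAL_DIRECTIONS: dict[str, str] = {
    "sigma": "greater",
    "gamma": "greater",
    "Cp": "greater",
    "Eg": "greater",
    "Eloc": "greater",
    "Lp": "less",
    "lambda": "less",
    "Q": "less",
}

#: Largest sample for which the Wilcoxon null distribution is enumerated exactly.
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_raw: float
    tail: str
    gate_p: float
    n: int
    degenerate: bool = False
    p_adjusted: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def normality_gate(differences: np.ndarray) -> tuple[float, str]:
    """Shapiro-Wilk on paired differences; returns (gate p, chosen test).

    Degenerate samples (all differences identical) fall back to the
    signed-rank test with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 paired differences")
    if np.ptp(d) == 0:
        warnings.warn("all paired differences identical; normality gate degenerate")
        return float("nan"), "wilcoxon_signed_rank"
    p = float(sps.shapiro(d).pvalue)
    return p, ("paired_t" if p >= 0.05 else "wilcoxon_signed_rank")


def _wilcoxon(d: np.ndarray, tail: str) -> tuple[float, float, int]:
    """Wilcoxon signed-rank on differences; zeros dropped (Wilcoxon convention).

    Exact null distribution for n <= 25 without ties in |d|, otherwise the
    normal approximation with continuity correction.
    """
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return 0.0, 1.0, 0
    if n < 3:
        return float("nan"), float("nan"), n
    ranks_tied = len(np.unique(np.abs(nz))) < n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and not ranks_tied) else "approx"
    res = sps.wilcoxon(
        nz, alternative=tail, zero_method="wilcox", correction=True, method=method
    )
    return float(res.statistic), float(res.pvalue), n


def paired_test(
    baseline: np.ndarray,
    followup: np.ndarray,
    tail: str = "two-sided",
    test_name: str | None = None,
) -> TestResult:
    """Normality-gated paired comparison of follow-up vs baseline.

    ``tail='greater'`` tests whether follow-up exceeds baseline. When
    ``test_name`` is given the gate's choice is overridden (the gate p-value is
    still reported).
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or len(b) < 3:
        raise ValueError("baseline and follow-up must be aligned with n >= 3")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(f))):
        raise ValueError("paired sample contains non-finite values")
    d = f - b
    if np.all(d == 0):
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, tail, float("nan"), 0, True)
    gate_p, chosen = normality_gate(d)
    if test_name is not None:
        chosen = test_name
    if chosen == "paired_t":
        res = sps.ttest_rel(f, b, alternative=tail)
        return TestResult("paired_t", float(res.statistic), float(res.pvalue), tail, gate_p, len(d))
    stat, p, n = _wilcoxon(d, tail)
    degenerate = not np.isfinite(p)
    return TestResult("wilcoxon_signed_rank", stat, p, tail, gate_p, n, degenerate)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation with midrank ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need aligned vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Spearman correlation undefined")
        return CorrelationResult(float("nan"), float("nan"), len(x))
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(x))


@dataclass
class StatisticalReport:
    """Results bundle of the full paired statistical plan."""

    global_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    inter_module_tests: pd.DataFrame
    intra_module_tests: pd.DataFrame
    implicated_modules: list[int]
    restricted_tests: pd.DataFrame
    correlations: pd.DataFrame
    directions: dict[str, str] = field(default_factory=lambda: dict(GLOBAL_DIRECTIONS))


def _paired_pivot(df: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot_table(index="subject", columns="session", values=value_col)
    if not {"baseline", "followup"} <= set(wide.columns):
        raise ValueError("both sessions required for a paired comparison")
    wide = wide.dropna()
    return wide["baseline"].to_numpy(), wide["followup"].to_numpy()


def _family_tests(
    df: pd.DataFrame, by: list[str], value_col: str, tail: str = "two-sided"
) -> pd.DataFrame:
    rows = []
    for key, grp in df.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        b, f = _paired_pivot(grp, value_col)
        r = paired_test(b, f, tail=tail)
        rows.append(
            dict(zip(by, key))
            | {
                "mean_baseline": float(np.mean(b)),
                "sd_baseline": float(np.std(b, ddof=1)),
                "mean_followup": float(np.mean(f)),
                "sd_followup": float(np.std(f, ddof=1)),
                "test": r.test_name,
                "statistic": r.statistic,
                "gate_p": r.gate_p,
                "p_raw": r.p_raw,
            }
        )
    return pd.DataFrame(rows)


def global_family_tests(global_auc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-tailed, uncorrected paired tests of the global AUC family.

    Directions come from the a priori hypothesis table GLOBAL_DIRECTIONS.
    ``global_auc`` is tidy: (subject, session, metric, auc).
    """
    rows = []
    for metric, direction in GLOBAL_DIRECTIONS.items():
        grp = global_auc[global_auc["metric"] == metric]
        if grp.empty:
            continue
        b, f = _paired_pivot(grp, "auc")
        r = paired_test(b, f, tail=direction)
        rows.append(
            {
                "metric": metric,
                "tail": direction,
                "mean_baseline": float(np.mean(b)),
                "sd_baseline": float(np.std(b, ddof=1)),
                "mean_followup": float(np.mean(f)),
                "sd_followup": float(np.std(f, ddof=1)),
                "test": r.test_name,
                "statistic": r.statistic,
                "gate_p": r.gate_p,
                "p_raw": r.p_raw,
                "significant": r.p_raw < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "tail", "mean_baseline", "sd_baseline", "mean_followup",
            "sd_followup", "test", "statistic", "gate_p", "p_raw", "significant",
        ],
    )


def run_statistical_plan(
    global_auc: pd.DataFrame,
    nodal_auc: pd.DataFrame,
    module_counts: pd.DataFrame,
    participation_table: pd.DataFrame,
    partition: ModularPartition,
    clinical: pd.DataFrame | None = None,
    trend_alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    roi_labels: tuple[str, ...] | None = None,
) -> StatisticalReport:
    """Run the full paired statistical plan on the pipeline's tables.

    Inputs are tidy tables: ``global_auc`` (subject, session, metric, auc),
    ``nodal_auc`` (subject, session, node, metric, auc), ``module_counts``
    (subject, session, module_a, module_b, count; a == b marks within-module),
    ``participation_table`` like ``nodal_auc`` with metric ``participation``.
    The restricted nodal family covers the nodes of the modules implicated by
    trend-level (uncorrected p < ``trend_alpha``) between-module changes.
    Clinical correlations are skipped with a notice when no table is supplied.
    """
    # (a) global one-tailed family, uncorrected
    global_tests = global_family_tests(global_auc, alpha=trend_alpha)

    # (b) whole-brain nodal family: two-tailed, BH-FDR across nodes per metric
    nodal_tests = _family_tests(nodal_auc, ["metric", "node"], "auc")
    if not nodal_tests.empty:
        nodal_tests["p_fdr"] = np.nan
        for metric in nodal_tests["metric"].unique():
            m = nodal_tests["metric"] == metric
            nodal_tests.loc[m, "p_fdr"] = fdr_adjust(nodal_tests.loc[m, "p_raw"].to_numpy())

    # (c) module-pair counts: separate BH families for inter and intra
    inter = module_counts[module_counts["module_a"] != module_counts["module_b"]]
    intra = module_counts[module_counts["module_a"] == module_counts["module_b"]]
    inter_tests = _family_tests(inter, ["module_a", "module_b"], "count")
    intra_tests = _family_tests(intra, ["module_a"], "count")
    for t in (inter_tests, intra_tests):
        if not t.empty:
            t["p_fdr"] = fdr_adjust(t["p_raw"].to_numpy())
            t["trend"] = t["p_raw"] < trend_alpha
            t["marker"] = np.where(t["trend"], "*", "")

    implicated: list[int] = []
    if not inter_tests.empty:
        flagged = inter_tests[inter_tests["trend"]]
        implicated = sorted(
            set(flagged["module_a"].astype(int)) | set(flagged["module_b"].astype(int))
        )

    # (d) restricted nodal family within implicated modules, BH per metric
    restricted_input = restricted_nodal_table(
        nodal_auc.rename(columns={"auc": "value"}),
        participation_table.rename(columns={"auc": "value"}),
        partition,
        set(implicated),
    )
    if restricted_input.empty:
        restricted_tests = pd.DataFrame(
            columns=["metric", "node", "test", "statistic", "gate_p", "p_raw", "p_fdr"]
        )
    else:
        restricted_tests = _family_tests(restricted_input, ["metric", "node"], "value")
        restricted_tests["p_fdr"] = np.nan
        for metric in restricted_tests["metric"].unique():
            m = restricted_tests["metric"] == metric
            restricted_tests.loc[m, "p_fdr"] = fdr_adjust(
                restricted_tests.loc[m, "p_raw"].to_numpy()
            )
    if roi_labels is not None and not restricted_tests.empty:
        restricted_tests["roi_label"] = [roi_labels[i] for i in restricted_tests["node"]]

    # (e) Spearman correlations of longitudinal changes
    corr_rows = []
    if clinical is None:
        warnings.warn("no clinical table supplied; correlations skipped")
    else:
        deltas = {}
        for metric in GLOBAL_DIRECTIONS:
            grp = global_auc[global_auc["metric"] == metric]
            if grp.empty:
                continue
            b, f = _paired_pivot(grp, "auc")
            deltas[metric] = f - b
        clin_deltas = {}
        for col in ("ftm_ab_treated", "ftm_c"):
            if col in clinical.columns:
                b, f = _paired_pivot(clinical, col)
                clin_deltas[col] = f - b
        for metric, dm in deltas.items():
            for col, dc in clin_deltas.items():
                if len(dm) == len(dc):
                    c = spearman(dm, dc)
                    corr_rows.append(
                        {"x": f"delta_{metric}", "y": f"delta_{col}", "rho": c.rho, "p": c.p, "n": c.n}
                    )
        # significant restricted betweenness nodes vs trending module-pair counts
        if not restricted_tests.empty and not inter_tests.empty:
            hits = restricted_tests[
                (restricted_tests["metric"] == "betweenness")
                & (restricted_tests["p_fdr"] < fdr_alpha)
            ]
            flagged = inter_tests[inter_tests["trend"]]
            for node in hits["node"]:
                grp = nodal_auc[(nodal_auc["metric"] == "betweenness") & (nodal_auc["node"] == node)]
                b, f = _paired_pivot(grp, "auc")
                d_bc = f - b
                label = roi_labels[node] if roi_labels is not None else f"node_{node}"
                for col, dc in clin_deltas.items():
                    if len(dc) == len(d_bc):
                        c = spearman(d_bc, dc)
                        corr_rows.append(
                            {
                                "x": f"delta_betweenness_{label}",
                                "y": f"delta_{col}",
                                "rho": c.rho,
                                "p": c.p,
                                "n": c.n,
                            }
                        )
                for row in flagged.itertuples(index=False):
                    pair = module_counts[
                        (module_counts["module_a"] == row.module_a)
                        & (module_counts["module_b"] == row.module_b)
                    ]
                    bb, ff = _paired_pivot(pair, "count")
                    if len(bb) == len(d_bc):
                        c = spearman(d_bc, ff - bb)
                        corr_rows.append(
                            {
                                "x": f"delta_betweenness_{label}",
                                "y": f"delta_count_m{row.module_a}m{row.module_b}",
                                "rho": c.rho,
                                "p": c.p,
                                "n": c.n,
                            }
                        )
    correlations = pd.DataFrame(corr_rows, columns=["x", "y", "rho", "p", "n"])

    return StatisticalReport(
        global_tests=global_tests,
        nodal_tests=nodal_tests,
        inter_module_tests=inter_tests,
        intra_module_tests=intra_tests,
        implicated_modules=implicated,
        restricted_tests=restricted_tests,
        correlations=correlations,
    )
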