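"""Paired statistical layer: gate, tests, FDR, correlations, full plan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from tremornet.modules import ModularPartition
from tremornet.stats import (
    GLOBAL_DIRECTIONS,
    fdr_adjust,
    normality_gate,
    paired_test,
    run_statistical_plan,
    spearman,
)


class TestNormalityGate:
    def test_normal_differences_mostly_choose_t(self):
        rng = np.random.default_rng(0)
        picks = [
            normality_gate(rng.standard_normal(30))[1] == "paired_t" for _ in range(200)
        ]
        assert 0.90 <= np.mean(picks) <= 0.99  # gate alpha 0.05

    def test_lognormal_differences_mostly_choose_wilcoxon(self):
        rng = np.random.default_rng(1)
        picks = [
            normality_gate(rng.lognormal(0, 1, size=30))[1] == "wilcoxon_signed_rank"
            for _ in range(100)
        ]
        assert np.mean(picks) > 0.9

    def test_degenerate_differences_fall_back_to_wilcoxon(self):
        with pytest.warns(UserWarning):
            gate_p, chosen = normality_gate(np.zeros(10))
        assert chosen == "wilcoxon_signed_rank"
        assert np.isnan(gate_p)


class TestPairedTest:
    def test_identical_sessions_give_p_one(self):
        b = np.arange(10.0)
        r = paired_test(b, b.copy(), tail="two-sided")
        assert r.p_raw == 1.0 and r.degenerate

    def test_shifted_copies_run_on_both_branches(self, rng):
        b = rng.standard_normal(20)
        f = b + 0.5 + rng.standard_normal(20) * 0.1
        for forced in ("paired_t", "wilcoxon_signed_rank"):
            r = paired_test(b, f, tail="greater", test_name=forced)
            assert 0.0 <= r.p_raw <= 1.0
            assert r.p_raw < 0.05  # clear shift

    def test_one_sided_greater_with_negative_shift_is_nonsignificant(self, rng):
        b = rng.standard_normal(15)
        f = b - 1.0
        for forced in ("paired_t", "wilcoxon_signed_rank"):
            assert paired_test(b, f, tail="greater", test_name=forced).p_raw >= 0.5

    @pytest.mark.parametrize("tail", ["two-sided", "greater", "less"])
    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_wilcoxon_matches_exact_sign_flip_enumeration(self, tail, n):
        rng = np.random.default_rng(n * 31 + len(tail))
        for _ in range(5):
            d = rng.standard_normal(n) + 0.3
            r = paired_test(np.zeros(n), d, tail=tail, test_name="wilcoxon_signed_rank")
            expected = oracles.wilcoxon_exact_oracle(d, tail)
            assert r.p_raw == pytest.approx(expected, abs=1e-12)

    def test_misaligned_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_test(np.zeros(4), np.zeros(5))


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.03])), [0.03])

    def test_hand_computed_step_up_example(self):
        np.testing.assert_allclose(
            fdr_adjust(np.array([0.005, 0.04, 0.03])), [0.015, 0.04, 0.04]
        )

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_matches_oracle(self, pvals):
        adj = fdr_adjust(np.array(pvals))
        assert np.all(adj >= np.array(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        np.testing.assert_allclose(adj, oracles.bh_oracle(pvals), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_tied_ranks_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 5.0, 5.0])
        assert spearman(x, y).rho == pytest.approx(oracles.spearman_oracle(x, y))

    def test_constant_vector_signaled(self):
        with pytest.warns(UserWarning):
            r = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(r.rho)


def _toy_tables(n_subjects=8, n_modules=6, seed=0):
    rng = np.random.default_rng(seed)
    subjects = [f"s{i}" for i in range(n_subjects)]
    g_rows, n_rows, c_rows, p_rows = [], [], [], []
    for s in subjects:
        for sess in ("baseline", "followup"):
            for m in GLOBAL_DIRECTIONS:
                g_rows.append((s, sess, m, rng.normal()))
            for node in range(6):
                for metric in ("degree", "betweenness"):
                    n_rows.append((s, sess, node, metric, rng.normal()))
                p_rows.append((s, sess, node, "participation", rng.uniform()))
            for a in range(n_modules):
                for b in range(a, n_modules):
                    c_rows.append((s, sess, a, b, int(rng.integers(0, 30))))
    return (
        pd.DataFrame(g_rows, columns=["subject", "session", "metric", "auc"]),
        pd.DataFrame(n_rows, columns=["subject", "session", "node", "metric", "auc"]),
        pd.DataFrame(c_rows, columns=["subject", "session", "module_a", "module_b", "count"]),
        pd.DataFrame(p_rows, columns=["subject", "session", "node", "metric", "auc"]),
    )


class TestStatisticalPlan:
    def test_six_modules_give_fifteen_inter_pairs_and_six_intra(self):
        g, n, c, p = _toy_tables()
        part = ModularPartition(np.array([0, 0, 1, 1, 2, 2]), 0.4)
        report = run_statistical_plan(g, n, c, p, part)
        assert len(report.inter_module_tests) == 15
        assert len(report.intra_module_tests) == 6
        assert report.inter_module_tests["p_raw"].between(0, 1).all()
        assert (report.inter_module_tests["p_fdr"] >= report.inter_module_tests["p_raw"] - 1e-15).all()

    def test_global_family_is_one_tailed_with_fixed_directions(self):
        g, n, c, p = _toy_tables(seed=3)
        part = ModularPartition(np.array([0, 0, 1, 1, 2, 2]), 0.4)
        report = run_statistical_plan(g, n, c, p, part)
        tails = dict(zip(report.global_tests["metric"], report.global_tests["tail"]))
        assert tails == GLOBAL_DIRECTIONS

    def test_missing_clinical_skips_correlations_with_notice(self):
        g, n, c, p = _toy_tables(seed=5)
        part = ModularPartition(np.array([0, 0, 1, 1, 2, 2]), 0.4)
        with pytest.warns(UserWarning, match="clinical"):
            report = run_statistical_plan(g, n, c, p, part, clinical=None)
        assert report.correlations.empty

    def test_nodal_fdr_scoped_within_metric(self):
        g, n, c, p = _toy_tables(seed=7)
        part = ModularPartition(np.array([0, 0, 1, 1, 2, 2]), 0.4)
        report = run_statistical_plan(g, n, c, p, part)
        for metric, grp in report.nodal_tests.groupby("metric"):
            np.testing.assert_allclose(
                grp["p_fdr"].to_numpy(),
                fdr_adjust(grp["p_raw"].to_numpy()),
                atol=1e-12,
            )
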