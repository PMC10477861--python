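"""Wilcoxon/BH funnel machinery against enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acpmine import (
    AbundanceMatrix,
    FunnelConfig,
    bh_adjust,
    log2_fold_change,
    presence_filter,
    run_funnel,
    simulate_null_abundance,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(a, b):
    """Two-sided p by full enumeration of equally likely rank splits."""
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = pooled.argsort().argsort() + 1
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            count += 1
    return count / total


def brute_force_bh(p):
    """Step-up BH from the definition, with explicit loops."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos, j in enumerate(order, start=1):
            if later_pos >= rank_pos:
                candidates.append(n * p[j] / later_pos)
        adj[i] = min(1.0, min(candidates))
    return adj


def make_matrix(values, groups, ids=None):
    ids = ids or [f"pep{i + 1}" for i in range(len(values))]
    cols = [f"s{i + 1}" for i in range(len(groups))]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=cols)
    return AbundanceMatrix(values=df, group_labels=pd.Series(groups, index=cols))


class TestPresenceFilter:
    def test_zero_rows_dropped(self):
        m = make_matrix([[0, 0], [0, 1], [2, 0], [0, 0], [1, 1]],
                        ["control", "case"])
        assert presence_filter(m) == ["pep2", "pep3", "pep5"]

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            presence_filter(make_matrix(np.empty((0, 0)), []))


class TestWilcoxon:
    def test_textbook_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_sets_p_one(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]) == 1.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 9)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            wilcoxon_rank_sum(np.exp(a), np.exp(b)))

    def test_exact_branch_matches_full_enumeration(self, rng):
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (2, 6), (5, 4)]:
            for _ in range(5):
                a = rng.normal(0, 1, n1)
                b = rng.normal(0.8, 1, n2)
                assert wilcoxon_rank_sum(a, b) == pytest.approx(
                    exact_rank_sum_p(a, b)), (a, b)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBHAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 25))
        assert bh_adjust(p) == pytest.approx(brute_force_bh(list(p)))

    def test_fdr_at_least_p(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change(7.0, 7.0) == 0.0

    def test_fourfold_with_small_pseudocount(self):
        assert log2_fold_change(4000.0, 1000.0, pseudocount=1e-6) == pytest.approx(
            2.0, abs=1e-5)

    def test_antisymmetric(self):
        assert log2_fold_change(30.0, 7.0, 0.5) == pytest.approx(
            -log2_fold_change(7.0, 30.0, 0.5))


class TestRunFunnel:
    def _toy_matrix(self):
        """Six peptides, 10+10 samples: one planted per direction, one flat,
        three absent."""
        rng = np.random.default_rng(5)
        n = 10
        ctrl_enriched = np.concatenate([1000 + rng.uniform(0, 9, n),
                                        10 + rng.uniform(0, 2, n)])
        case_enriched = np.concatenate([10 + rng.uniform(0, 2, n),
                                        1000 + rng.uniform(0, 9, n)])
        flat = np.full(2 * n, 400.0)
        zeros = np.zeros(2 * n)
        values = np.vstack([ctrl_enriched, case_enriched, flat, zeros, zeros, zeros])
        return make_matrix(values, ["control"] * n + ["case"] * n)

    def test_hand_executed_toy_funnel(self):
        results, report = run_funnel(self._toy_matrix())
        assert report.counts == {"input": 6, "present": 3, "significant": 2,
                                 "fc_pass": 2, "ctrl_enriched": 1, "abundant": 1}
        assert report.retained_ids["abundant"] == ["pep1"]
        row = results.set_index("peptide_id").loc["pep1"]
        assert row["enriched_in"] == "control"
        assert row["log2fc"] > 2

    def test_vacuous_filters_keep_all_positive_lfc(self):
        m = self._toy_matrix()
        cfg = FunnelConfig(fdr_threshold=1.0000001, log2fc_cutoff=1e-9,
                           abundance_floor=1e-12)
        _, report = run_funnel(m, cfg)
        results, _ = run_funnel(m)
        assert report.counts["abundant"] == sum(
            1 for _, r in results.iterrows() if r["log2fc"] > 1e-9)

    def test_all_zero_matrix_all_stages_zero(self):
        m = make_matrix(np.zeros((4, 6)), ["control"] * 3 + ["case"] * 3)
        _, report = run_funnel(m)
        assert all(report.counts[s] == 0 for s in
                   ["present", "significant", "fc_pass", "ctrl_enriched", "abundant"])

    def test_counts_non_increasing(self, rng):
        vals = rng.lognormal(3, 2, size=(40, 16)) * rng.integers(0, 2, (40, 1))
        m = make_matrix(vals, ["control"] * 8 + ["case"] * 8)
        _, report = run_funnel(m)
        counts = [report.counts[s] for s in
                  ["input", "present", "significant", "fc_pass",
                   "ctrl_enriched", "abundant"]]
        assert counts == sorted(counts, reverse=True)

    def test_single_group_errors(self):
        m = make_matrix([[1, 2]], ["control", "control"])
        with pytest.raises(ValueError):
            run_funnel(m)

    def test_global_null_fdr_stage_controlled(self):
        # small version of the 500-peptide null check (full size in acceptance)
        m = simulate_null_abundance(200, 15, 15, seed=99)
        _, report = run_funnel(m)
        frac = report.counts["significant"] / report.counts["present"]
        se = np.sqrt(0.05 * 0.95 / 200)
        assert frac <= 0.05 + 3 * se
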