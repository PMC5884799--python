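import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from consensusde.differential import (
    ThresholdConfig,
    bh_adjust,
    choose_pvalue_column,
    log2_fold_change,
    mark_significant,
    threshold_significant,
    two_sample_t,
)


def bh_oracle(p):
    """Brute-force BH step-up: adj(i) = min over j>=i of p(j)·m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank, m + 1)
        ]
        adj_sorted[rank - 1] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestTwoSampleT:
    def test_identical_groups_give_t_zero_p_one(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_pooled_matches_closed_form_oracle(self):
        # hand-derived: diff 10, sp^2 = 1, se = sqrt(2/3), t = 12.247, df = 4
        res = two_sample_t([11, 12, 13], [1, 2, 3], variant="pooled")
        assert res.statistic == pytest.approx(12.24744871391589, rel=1e-12)
        assert res.df == 4
        assert res.pvalue == pytest.approx(0.0002552167494419268, rel=1e-12)

    def test_swapping_groups_negates_t_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        fwd, rev = two_sample_t(a, b), two_sample_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.pvalue == pytest.approx(rev.pvalue)

    def test_welch_df_differs_from_pooled_under_unequal_variance(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 4)
        assert two_sample_t(a, b, "welch").df != two_sample_t(a, b, "pooled").df

    def test_constant_equal_groups_degenerate_contract(self):
        res = two_sample_t([5, 5, 5], [5, 5, 5])
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_too_short_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_sample_t([1.0], [1, 2, 3])


class TestBhAdjust:
    def test_single_pvalue_is_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_evaluated_step_up(self):
        # min over j>=i of p(j)·m/j: all collapse to 0.04·4/4 = 0.04
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_capped(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 21))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_output_dominates_input_and_preserves_ranks(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # order preservation: sorting by p never decreases adjusted values
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestChoosePvalueColumn:
    def test_poor_dataset_falls_back_to_raw(self):
        chosen, used_adjusted = choose_pvalue_column(
            [0.01, 0.2, 0.5], [0.2, 0.6, 0.9]
        )
        assert not used_adjusted
        np.testing.assert_allclose(chosen, [0.01, 0.2, 0.5])

    def test_any_adjusted_hit_keeps_adjusted(self):
        chosen, used_adjusted = choose_pvalue_column([0.001, 0.3], [0.01, 0.6])
        assert used_adjusted
        np.testing.assert_allclose(chosen, [0.01, 0.6])

    def test_empty_vectors_vacuously_use_adjusted(self):
        chosen, used_adjusted = choose_pvalue_column([], [])
        assert used_adjusted and chosen.size == 0


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "case,control,scale,expected",
        [
            ([6, 6], [4, 4], "already_log2", 2.0),
            ([8, 8], [2, 2], "linear", 2.0),
            ([3, 4], [3, 4], "already_log2", 0.0),
        ],
    )
    def test_examples(self, case, control, scale, expected):
        assert log2_fold_change(case, control, scale) == pytest.approx(expected)

    def test_linear_scale_requires_positive_means(self):
        with pytest.raises(ValueError, match="positive"):
            log2_fold_change([1, 2], [-3, -4], scale="linear")


class TestThreshold:
    def test_strict_inequalities_at_both_boundaries(self, make_table):
        table = make_table(
            [
                ("keep", 1.2, 0.01),
                ("lfc_at_cut", 1.0, 0.01),
                ("p_at_cut", 2.5, 0.05),
                ("keep_down", -1.5, 0.04),
            ]
        )
        out = threshold_significant(table, ThresholdConfig())
        assert list(out.records["source_id"]) == ["keep", "keep_down"]

    def test_idempotent(self, make_table):
        table = make_table([("a", 1.2, 0.01), ("b", 0.5, 0.9)])
        once = threshold_significant(table)
        twice = threshold_significant(once)
        assert list(once.records["source_id"]) == list(twice.records["source_id"])

    def test_mark_significant_prefers_chosen_p(self, make_table):
        table = make_table([("a", 2.0, 0.5)])
        records = table.records.assign(chosen_p=[0.01])
        marked = mark_significant(records, ThresholdConfig())
        assert marked["passed"].all()


class TestNullCalibration:
    def test_raw_pvalue_rate_near_alpha_under_null(self, rng):
        """Fraction of null genes with p < 0.05 lies in the binomial CI."""
        n_genes, n = 4000, 10
        case = rng.normal(8, 1, size=(n_genes, n))
        control = rng.normal(8, 1, size=(n_genes, n))
        p = stats.ttest_ind(case, control, axis=1).pvalue
        rate = (p < 0.05).mean()
        half = 3 * np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(rate - 0.05) < half
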