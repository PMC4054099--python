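"""Expression calls, breadth classes and fraction-comparison statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import driverlens as dl
from driverlens.errors import ValidationError
from oracles import chi2_closed_form, fisher_two_sided_enum


def _probe_table(pvals, gene="G1", context="t1"):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(pvals))],
            "gene_id": gene,
            "context_id": context,
            "detection_p": pvals,
        }
    )


class TestCallExpression:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.20], "expressed"),  # 1 of 2 meets "at least half"
            ([0.06, 0.2, 0.9], "not_expressed"),
            ([0.01, 0.02, 0.9], "expressed"),  # 2 of 3 >= 1.5
            ([0.04], "expressed"),
            ([0.05], "not_expressed"),  # strict p < alpha
        ],
    )
    def test_at_least_half_rule(self, pvals, expected):
        m = dl.call_expression(_probe_table(pvals))
        assert m.call("t1", "G1") == expected

    def test_gene_without_probes_is_no_data(self):
        m = dl.call_expression(_probe_table([0.01]), genes=["G2"])
        assert m.call("t1", "G2") == "no_data"

    def test_empty_table_gives_empty_matrix(self):
        m = dl.call_expression(_probe_table([]))
        assert m.calls.shape == (0, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        pvals=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6),
        alpha_lo=st.floats(0.01, 0.5),
        alpha_hi=st.floats(0.01, 0.5),
    )
    def test_monotone_in_alpha(self, pvals, alpha_lo, alpha_hi):
        """Raising alpha never turns an expressed call into not_expressed."""
        lo, hi = sorted([alpha_lo, alpha_hi])
        m_lo = dl.call_expression(_probe_table(pvals), alpha=lo)
        m_hi = dl.call_expression(_probe_table(pvals), alpha=hi)
        if m_lo.call("t1", "G1") == "expressed":
            assert m_hi.call("t1", "G1") == "expressed"


class TestBreadth:
    @pytest.mark.parametrize(
        "n_expressed,expected",
        [
            (109, "housekeeping"),
            (108, "housekeeping"),
            (107, "housekeeping"),
            (106, "intermediate"),
            (50, "intermediate"),
            (28, "intermediate"),
            (27, "tissue_selective"),
            (20, "tissue_selective"),
            (0, "tissue_selective"),
        ],
    )
    def test_class_boundaries_on_109_tissues(self, n_expressed, expected):
        assert dl.classify_breadth(n_expressed, 109) == expected

    def test_cutoffs_at_109_are_107_and_27(self):
        cuts = dl.breadth_cutoffs(109)
        assert cuts == {"housekeeping_min": 107, "tissue_selective_max": 27}

    def test_zero_total_is_error(self):
        with pytest.raises(ValidationError):
            dl.classify_breadth(0, 0)


def _matrix(group_counts, rest_counts):
    """Build a one-context call matrix realizing (expressed, total) per group."""
    ge, gt = group_counts
    re_, rt = rest_counts
    genes, calls = [], []
    for i in range(gt):
        genes.append(f"g{i}")
        calls.append("expressed" if i < ge else "not_expressed")
    for i in range(rt):
        genes.append(f"r{i}")
        calls.append("expressed" if i < re_ else "not_expressed")
    df = pd.DataFrame([calls], index=["c"], columns=genes)
    group = {f"g{i}" for i in range(gt)}
    rest = {f"r{i}" for i in range(rt)}
    return dl.ExpressionCallMatrix(calls=df), group, rest


class TestFractionComparison:
    def test_equal_proportions(self):
        m, group, rest = _matrix((5, 10), (50, 100))
        cmp = dl.expressed_fraction_comparison(group, rest, "c", m)
        assert cmp.log2ratio == 0.0
        assert cmp.chi2_stat == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_matches_closed_form_chi2(self):
        m, group, rest = _matrix((8, 10), (40, 100))
        cmp = dl.expressed_fraction_comparison(group, rest, "c", m)
        assert cmp.chi2_stat == pytest.approx(chi2_closed_form(8, 2, 40, 60))
        assert np.array_equal(cmp.counts, [[8, 2], [40, 60]])

    def test_zero_fraction_leaves_log2ratio_undefined(self):
        m, group, rest = _matrix((0, 10), (40, 100))
        cmp = dl.expressed_fraction_comparison(group, rest, "c", m)
        assert cmp.log2ratio is None
        assert cmp.defined
        assert np.array_equal(cmp.counts, [[0, 10], [40, 60]])

    def test_swap_negates_log2ratio_keeps_p(self):
        m, group, rest = _matrix((8, 10), (40, 100))
        fwd = dl.expressed_fraction_comparison(group, rest, "c", m)
        rev = dl.expressed_fraction_comparison(rest, group, "c", m)
        assert rev.log2ratio == pytest.approx(-fwd.log2ratio)
        assert rev.chi2_stat == pytest.approx(fwd.chi2_stat)
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_no_data_genes_leave_both_sides(self):
        calls = pd.DataFrame(
            [["expressed", "no_data", "expressed", "not_expressed"]],
            index=["c"],
            columns=["g0", "g1", "r0", "r1"],
        )
        m = dl.ExpressionCallMatrix(calls=calls)
        cmp = dl.expressed_fraction_comparison({"g0", "g1"}, {"r0", "r1"}, "c", m)
        assert cmp.f_group == 1.0  # g1 excluded entirely
        assert np.array_equal(cmp.counts, [[1, 0], [1, 1]])

    def test_empty_group_flagged_not_raised(self):
        calls = pd.DataFrame([["no_data", "expressed"]], index=["c"], columns=["g0", "r0"])
        m = dl.ExpressionCallMatrix(calls=calls)
        cmp = dl.expressed_fraction_comparison({"g0"}, {"r0"}, "c", m)
        assert not cmp.defined and cmp.p_value is None

    def test_highly_expressed_uses_context_median(self):
        calls = pd.DataFrame(
            [["expressed"] * 5], index=["c"], columns=[f"x{i}" for i in range(5)]
        )
        level = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0]], index=["c"], columns=calls.columns
        )
        m = dl.ExpressionCallMatrix(calls=calls, level=level)
        # median is 3; only levels 4 and 5 are "high"
        assert m.highly_expressed_genes("c") == {"x3", "x4"}
        cmp = dl.expressed_fraction_comparison(
            {"x3", "x4"}, {"x0", "x1", "x2"}, "c", m, mode="highly_expressed"
        )
        assert cmp.f_group == 1.0 and cmp.f_rest == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_chi2_property_against_closed_form(self, a, b, c, d):
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return
        stat, _ = dl.expression.chi2_2x2(table)
        assert stat == pytest.approx(chi2_closed_form(a, b, c, d), abs=1e-9)


class TestFisher:
    def test_diagonal_table(self):
        _, p = dl.class_enrichment_fisher([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)

    def test_uniform_table(self):
        _, p = dl.class_enrichment_fisher([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_all_zero_is_error(self):
        with pytest.raises(ValidationError):
            dl.class_enrichment_fisher([[0, 0], [0, 0]])

    def test_zero_margin_odds_ratio_undefined(self):
        odds, p = dl.class_enrichment_fisher([[0, 0], [1, 2]])
        assert odds is None and p == pytest.approx(1.0)

    def test_against_hypergeometric_enumeration(self):
        for table in [(3, 1, 1, 4), (2, 5, 6, 1), (1, 0, 3, 2), (4, 4, 4, 4)]:
            _, p = dl.class_enrichment_fisher(np.array(table).reshape(2, 2))
            assert p == pytest.approx(fisher_two_sided_enum(*table), rel=1e-9)


class TestBreadthComparison:
    def test_identical_groups_p_one(self):
        res = dl.compare_breadth_distributions([1, 2, 3], [1, 2, 3])
        assert res["wilcoxon_p"] == pytest.approx(1.0)

    def test_complete_separation_exact_tail(self):
        res = dl.compare_breadth_distributions(
            [1, 2, 3, 4, 5], [101, 102, 103, 104, 105]
        )
        assert res["wilcoxon_p"] == pytest.approx(2 / math.comb(10, 5))
        assert res["median_a"] == 3 and res["median_b"] == 103

    def test_undersized_group_is_error(self):
        with pytest.raises(ValidationError):
            dl.compare_breadth_distributions([1, 2], [1, 2, 3])


def test_volcano_rows_shape(small_cohort):
    bundle, _ = small_cohort
    matrix = bundle.tissue_expression
    genes = set(matrix.genes)
    known = set(bundle.known_cancer_set) & genes
    rest = genes - known
    contexts = matrix.contexts[:3]
    df = dl.volcano_rows({"known": known}, rest, contexts, matrix)
    assert list(df["context"]) == contexts
    assert df["defined"].all()
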