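import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reosig as rs
from reosig.pair_engine import GenePairRecord, PairScreenParams

from .conftest import make_labels
from . import oracles


class TestCountAndEnumerate:
    def test_small_universe_enumeration(self):
        pairs = list(rs.enumerate_pairs(["A", "B"], ["A", "B", "C", "D"]))
        assert pairs == [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]
        assert rs.count_candidate_pairs(2, 4) == 5

    def test_all_marked_reduces_to_all_pairs(self):
        assert rs.count_candidate_pairs(6, 6) == 15
        assert rs.count_candidate_pairs(0, 100) == 0

    @given(st.integers(0, 30), st.integers(0, 60), st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_count_matches_bruteforce_and_stream(self, n_marked, n_extra, seed):
        n_total = n_marked + n_extra
        universe = [f"g{i:03d}" for i in range(n_total)]
        rng = np.random.default_rng(seed)
        marked = list(rng.choice(universe, size=n_marked, replace=False)) if n_marked else []
        expected = oracles.count_pairs_bruteforce(marked, universe)
        assert rs.count_candidate_pairs(n_marked, n_total) == expected
        stream = list(rs.enumerate_pairs(marked, universe))
        assert len(stream) == expected
        assert len(set(stream)) == len(stream)
        assert all(a < b for a, b in stream)
        assert stream == sorted(stream)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rs.count_candidate_pairs(-1, 5)
        with pytest.raises(ValueError):
            rs.count_candidate_pairs(7, 5)
        with pytest.raises(ValueError):
            list(rs.enumerate_pairs(["zz"], ["a", "b"]))


class TestComputeEd:
    def test_hand_computed_value(self):
        expr = rs.ExpressionMatrix(pd.DataFrame(
            {"s1": [3.0, 1.0], "s2": [5.0, 3.0], "s3": [2.0, 3.0], "s4": [4.0, 3.0]},
            index=["gi", "gj"]))
        labels = make_labels(["s1", "s2", "s3", "s4"], [True, True, False, False])
        # responder diffs {2, 2}; non-responder diffs {-1, 1} -> ED = 2 - 0 = 2
        assert rs.compute_ed(("gi", "gj"), expr, labels) == pytest.approx(2.0)
        assert rs.compute_ed(("gj", "gi"), expr, labels) == pytest.approx(-2.0)

    def test_zero_ed_pair_rejected_by_orientation(self):
        expr = rs.ExpressionMatrix(pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [1.0, 2.0], "s3": [2.0, 1.0], "s4": [1.0, 2.0]},
            index=["a", "b"]))
        labels = make_labels(["s1", "s2", "s3", "s4"], [True, True, False, False])
        assert rs.compute_ed(("a", "b"), expr, labels) == 0.0
        assert rs.orient_pair(("a", "b"), expr, labels) is None

    def test_empty_group_raises(self, tiny_expr):
        labels = make_labels(["s1", "s2"], [True, True])
        with pytest.raises(ValueError, match="non-empty"):
            rs.compute_ed(("A", "B"), tiny_expr, labels)


class TestOrientPair:
    def test_negative_ed_swaps_genes(self):
        expr = rs.ExpressionMatrix(pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [2.0, 5.0], "s3": [4.0, 1.0], "s4": [5.0, 2.0]},
            index=["x", "y"]))
        labels = make_labels(["s1", "s2", "s3", "s4"], [True, True, False, False])
        rec = rs.orient_pair(("x", "y"), expr, labels)
        assert (rec.gene_i, rec.gene_j) == ("y", "x")
        assert rec.ed > 0
        assert rec.tp == 2 and rec.tn == 2 and rec.fp == 0 and rec.fn == 0

    def test_all_retained_records_have_positive_ed(self, sim47, labels47):
        _, expr, _, _ = sim47
        genes = expr.gene_ids[:50]
        pairs = [(genes[i], genes[j]) for i in range(20) for j in range(i + 1, 20)]
        for p in pairs:
            rec = rs.orient_pair(p, expr, labels47)
            if rec is not None:
                assert rec.ed > 0
                assert rec.ed == pytest.approx(
                    rs.compute_ed((rec.gene_i, rec.gene_j), expr, labels47))


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        expr = rs.ExpressionMatrix(pd.DataFrame(
            {f"s{i}": [float(v), 0.0] for i, v in enumerate([1, 2, 3, 1, 2, 3])},
            index=["a", "b"]))
        labels = make_labels([f"s{i}" for i in range(6)],
                             [True, True, True, False, False, False])
        assert rs.wilcoxon_reo_test(("a", "b"), expr, labels) == pytest.approx(1.0)

    def test_complete_separation_three_vs_three(self):
        expr = rs.ExpressionMatrix(pd.DataFrame(
            {f"s{i}": [float(v), 0.0] for i, v in enumerate([4, 5, 6, 1, 2, 3])},
            index=["a", "b"]))
        labels = make_labels([f"s{i}" for i in range(6)],
                             [True, True, True, False, False, False])
        # exact two-sided p = 2 / C(6,3) = 0.1
        assert rs.wilcoxon_reo_test(("a", "b"), expr, labels) == pytest.approx(0.1)

    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_p_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(size=n1 + n2)
        expr = rs.ExpressionMatrix(pd.DataFrame(
            {f"s{i}": [d, 0.0] for i, d in enumerate(diffs)}, index=["a", "b"]))
        labels = make_labels([f"s{i}" for i in range(n1 + n2)],
                             [True] * n1 + [False] * n2)
        p = rs.wilcoxon_reo_test(("a", "b"), expr, labels)
        expected = oracles.wilcoxon_exact_two_sided(diffs[:n1], diffs[n1:])
        assert p == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform_of_diffs(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(size=12)
        labels = make_labels([f"s{i}" for i in range(12)], [True] * 7 + [False] * 5)

        def build(d):
            return rs.ExpressionMatrix(pd.DataFrame(
                {f"s{i}": [v, 0.0] for i, v in enumerate(d)}, index=["a", "b"]))

        p1 = rs.wilcoxon_reo_test(("a", "b"), build(diffs), labels)
        p2 = rs.wilcoxon_reo_test(("a", "b"), build(np.exp(diffs)), labels)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestBinomialFilter:
    def test_perfect_accuracy_closed_form(self):
        rec = GenePairRecord("a", "b", ed=1.0, tp=36, tn=11, fp=0, fn=0, f_score=1.0)
        ok, p = rs.binomial_filter(rec, PairScreenParams(binomial_null_p=36 / 47))
        assert ok
        assert p == pytest.approx((36 / 47) ** 47, rel=1e-9)
        assert p == pytest.approx(oracles.binomial_upper_tail(47, 47, 36 / 47), rel=1e-9)

    @given(st.integers(5, 60), st.integers(0, 60), st.floats(0.3, 0.95))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_p_matches_tail_sum_oracle(self, n, correct_raw, p0):
        correct = min(correct_raw, n)
        tp = correct
        fn = n - correct
        rec = GenePairRecord("a", "b", ed=1.0, tp=tp, tn=0, fp=0, fn=fn, f_score=correct / n)
        _, p = rs.binomial_filter(rec, PairScreenParams(binomial_null_p=p0))
        assert p == pytest.approx(oracles.binomial_upper_tail(correct, n, p0), rel=1e-9)

    def test_expected_accuracy_under_null_fails(self):
        # correct count == n*p0 exactly: upper tail is far from significant
        rec = GenePairRecord("a", "b", ed=1.0, tp=30, tn=0, fp=0, fn=10, f_score=0.75)
        ok, p = rs.binomial_filter(rec, PairScreenParams(binomial_null_p=0.75))
        assert not ok
        assert p > 0.4

    def test_degenerate_null_never_passes(self):
        rec = GenePairRecord("a", "b", ed=1.0, tp=47, tn=0, fp=0, fn=0, f_score=1.0)
        ok, p = rs.binomial_filter(rec, PairScreenParams(binomial_null_p=1.0))
        assert not ok and p == pytest.approx(1.0)

    def test_default_null_is_majority_class_rate(self):
        rec = GenePairRecord("a", "b", ed=1.0, tp=33, tn=11, fp=0, fn=3, f_score=44 / 47)
        _, p = rs.binomial_filter(rec)
        assert p == pytest.approx(oracles.binomial_upper_tail(44, 47, 36 / 47), rel=1e-9)


class TestPairFScore:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (33, 11, 0, 3, 44 / 47),  # 0.94 at 2 dp
        (10, 5, 0, 0, 1.0),
        (0, 0, 5, 10, 0.0),
    ])
    def test_accuracy_formula(self, tp, tn, fp, fn, expected):
        rec = GenePairRecord("a", "b", ed=1.0, tp=tp, tn=tn, fp=fp, fn=fn, f_score=0.0)
        assert rs.pair_f_score(rec) == pytest.approx(expected)
        if (tp, tn, fp, fn) == (33, 11, 0, 3):
            assert round(rs.pair_f_score(rec), 2) == 0.94

    def test_empty_counts_raise(self):
        rec = GenePairRecord("a", "b", ed=1.0, tp=0, tn=0, fp=0, fn=0, f_score=0.0)
        with pytest.raises(ValueError):
            rs.pair_f_score(rec)


class TestScreenPairs:
    def test_batch_agrees_with_single_pair_path(self, sim47, labels47):
        _, expr, _, truth = sim47
        genes = expr.gene_ids[:30]
        pairs = list(rs.enumerate_pairs(genes[:10], genes)) + truth.planted_pairs
        records, funnel = rs.screen_pairs(
            pairs, expr, labels47,
            PairScreenParams(wilcoxon_p_threshold=0.5, binomial_alpha=0.999),
        )
        assert funnel["input"] == len(pairs)
        for rec in records[:40]:
            single = rs.orient_pair((rec.gene_i, rec.gene_j), expr, labels47)
            assert (single.tp, single.tn, single.fp, single.fn) == \
                   (rec.tp, rec.tn, rec.fp, rec.fn)
            assert rec.ed == pytest.approx(single.ed)
            assert rec.wilcoxon_p == pytest.approx(
                rs.wilcoxon_reo_test((rec.gene_i, rec.gene_j), expr, labels47))
            _, bp = rs.binomial_filter(rec)
            assert rec.binomial_p == pytest.approx(bp)

    def test_records_sorted_by_accuracy_then_pvalue(self, sim47, labels47):
        _, expr, _, truth = sim47
        pairs = list(rs.enumerate_pairs(expr.gene_ids[:20], expr.gene_ids[:60]))
        records, _ = rs.screen_pairs(
            pairs, expr, labels47,
            PairScreenParams(wilcoxon_p_threshold=0.9, binomial_alpha=0.999))
        keys = [r.sort_key() for r in records]
        assert keys == sorted(keys)

    def test_votes_invariant_under_monotone_distortion(self, sim47, labels47):
        _, expr, _, truth = sim47
        distorted = rs.apply_monotone_distortion(expr, seed=99)
        pairs = truth.planted_pairs + list(
            rs.enumerate_pairs(expr.gene_ids[:10], expr.gene_ids[:40]))
        votes_a = rs.pair_engine.pair_votes(pairs, expr, labels47.sample_ids)
        votes_b = rs.pair_engine.pair_votes(pairs, distorted, labels47.sample_ids)
        np.testing.assert_array_equal(votes_a, votes_b)
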