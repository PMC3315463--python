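"""Rank aggregation, splicing efficiency, and hypergeometric enrichment."""

from fractions import Fraction
from itertools import accumulate
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import splicescreen as ss
from splicescreen.analysis import hypergeom_tail


def exact_tail(N, K, n, k):
    """Exact-arithmetic oracle: suffix sum of the hypergeometric pmf."""
    hi = min(K, n)
    if k > hi:
        return Fraction(0)
    if k <= 0:
        return Fraction(1)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    return Fraction(num, comb(N, n))


class TestRankStrains:
    def test_descending_ranks(self):
        v = pd.Series({"a": 4.0, "b": 2.0, "c": 1.0})
        assert ss.rank_strains(v).tolist() == [1.0, 2.0, 3.0]

    def test_average_rank_ties(self):
        v = pd.Series({"a": 3.0, "b": 3.0, "c": 1.0})
        assert ss.rank_strains(v).tolist() == [1.5, 1.5, 3.0]

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.normal(size=1000), index=[f"s{i}" for i in range(1000)])
        ranks = ss.rank_strains(v)
        order = v.sort_values(ascending=False).index
        expected = pd.Series(np.arange(1, 1001, dtype=float), index=order)
        pd.testing.assert_series_equal(
            ranks.sort_index(), expected.sort_index(), check_names=False
        )

    def test_missing_strains_excluded(self):
        v = pd.Series({"a": 1.0, "b": np.nan})
        assert "b" not in ss.rank_strains(v).index


class TestCompositeRank:
    def _ranks(self, data):
        return pd.DataFrame(data).T

    def test_rank_one_everywhere_is_global_minimum(self):
        ranks = self._ranks(
            {"best": [1, 1, 1, 1, 1], "mid": [2, 3, 2, 3, 2], "low": [3, 2, 3, 2, 3]}
        )
        out = ss.composite_rank(ranks)
        assert out.index[0] == "best"
        assert out.loc["best", "composite_rank"] == 1.0

    def test_hand_mean(self):
        ranks = self._ranks({"s": [1, 3, 5, 7, 9]})
        assert ss.composite_rank(ranks, min_targets=5).loc["s", "composite_rank"] == 5.0

    def test_target_order_symmetry(self):
        ranks = self._ranks({"s": [1, 3, 5], "t": [2, 2, 2]})
        permuted = ranks[ranks.columns[::-1]]
        a = ss.composite_rank(ranks)["composite_rank"]
        b = ss.composite_rank(permuted)["composite_rank"]
        pd.testing.assert_series_equal(a, b)

    def test_below_min_targets_flagged_and_last(self):
        ranks = self._ranks(
            {"full": [5, 5, 5], "sparse": [1.0, np.nan, np.nan]}
        )
        out = ss.composite_rank(ranks, min_targets=3)
        assert not out.loc["sparse", "enough_targets"]
        assert out.index[-1] == "sparse"


class TestSplicingEfficiency:
    def test_equal_levels_give_one(self):
        assert ss.splicing_efficiency(1.0, 1.0) == 1.0

    def test_direct_division(self):
        assert ss.splicing_efficiency(2.0, 1.0) == 2.0

    def test_nonpositive_total_is_missing(self):
        assert np.isnan(ss.splicing_efficiency(2.0, 0.0))

    def test_yield_invariance_composition(self):
        # Rel is yield-invariant, so the index built from two Rel values is too
        assert ss.splicing_efficiency(3.0 * 2, 1.5 * 2) == ss.splicing_efficiency(3.0, 1.5)


class TestEnrichmentTest:
    def test_certain_event(self):
        # every background strain annotated: top list must be fully annotated
        assert ss.enrichment_test(100, 100, 10, 10).p == pytest.approx(1.0)

    def test_single_term_tail(self):
        res = ss.enrichment_test(5122, 68, 14, 14)
        expected = comb(68, 14) / comb(5122, 14)
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_matches_exact_arithmetic_small(self):
        for N, K, n, k in [(20, 5, 8, 3), (60, 30, 30, 20), (45, 10, 12, 0)]:
            assert ss.enrichment_test(N, K, n, k).p == pytest.approx(
                float(exact_tail(N, K, n, k)), rel=1e-12
            )

    def test_matches_scipy_upper_tail(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 5000))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert ss.enrichment_test(N, K, n, k).p == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), rel=1e-8, abs=1e-280
            )

    def test_monotone_in_k(self):
        ps = [ss.enrichment_test(500, 40, 60, k).p for k in range(0, 41)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            ss.enrichment_test(10, 5, 4, 6)
        with pytest.raises(ValueError):
            ss.enrichment_test(10, 12, 4, 2)

    @given(
        N=st.integers(1, 60),
        data=st.data(),
    )
    @settings(deadline=None, max_examples=100)
    def test_property_exact_arithmetic_equivalence(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert ss.enrichment_test(N, K, n, k).p == pytest.approx(
            float(exact_tail(N, K, n, k)), rel=1e-10, abs=0
        )


class TestGeneSetEnrichment:
    def test_counts_and_p(self):
        ordered = [f"s{i}" for i in range(100)]
        sets = {"hits": {f"s{i}" for i in range(10)}}
        table = ss.gene_set_enrichment(ordered, sets, top_ns=(10,))
        row = table.iloc[0]
        assert (row["N"], row["K"], row["n"], row["k"]) == (100, 10, 10, 10)
        assert row["p"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_empty_set_skipped(self):
        table = ss.gene_set_enrichment(["a", "b"], {"none": {"zzz"}}, top_ns=(1,))
        assert table.empty


class TestCandidateReport:
    def _sam_tables(self):
        strains = [f"s{i}" for i in range(6)]
        t1 = pd.DataFrame(
            {
                "strain_id": strains,
                "d": [5.0, 4.0, 0.1, 0.0, -0.2, 0.3],
                "call": ["positive", "positive", "none", "none", "none", "none"],
            }
        )
        t2 = pd.DataFrame(
            {
                "strain_id": strains,
                "d": [4.5, 0.2, 0.1, 0.0, -0.1, 6.0],
                "call": ["positive", "none", "none", "none", "none", "positive"],
            }
        )
        return {"U3_pre": t1, "TUB3_pre": t2}

    def test_ordering_by_max_d(self):
        report = ss.candidate_report(self._sam_tables())
        cands = report["candidates"]
        assert cands.index.tolist() == ["s5", "s0", "s1"]
        assert np.all(np.diff(cands["max_d"]) <= 0)

    def test_single_target_hit_keeps_none_calls_elsewhere(self):
        report = ss.candidate_report(self._sam_tables())
        row = report["candidates"].loc["s5"]
        assert row["call_TUB3_pre"] == "positive"
        assert row["call_U3_pre"] == "none"
        assert row["n_significant_targets"] == 1

    def test_no_significant_strains_gives_empty_report(self):
        strains = ["a", "b"]
        t = pd.DataFrame({"strain_id": strains, "d": [0.1, -0.1], "call": ["none", "none"]})
        report = ss.candidate_report({"U3_pre": t})
        assert report["candidates"].empty

    def test_spiked_set_enriched_in_top_list(self):
        rng = np.random.default_rng(0)
        n = 500
        strains = [f"s{i:03d}" for i in range(n)]
        d = rng.normal(0, 1, size=n)
        spiked = set(strains[:20])
        d[:20] += 8.0
        calls = np.where(d > 5, "positive", "none")
        t = pd.DataFrame({"strain_id": strains, "d": d, "call": calls})
        report = ss.candidate_report(
            {"U3_pre": t}, gene_sets={"spiked": spiked}, top_ns=(50,)
        )
        assert report["enrichment"].iloc[0]["p"] < 1e-10
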