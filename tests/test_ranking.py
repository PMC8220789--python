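"""Relative Index, subclass ranking, and Goodman-Kruskal gamma."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import delphiframe as df
from delphiframe.errors import InsufficientDataError
from delphiframe.ranking import _pair_counts


def naive_pair_counts(x, y):
    """Double-loop concordant/discordant enumeration (oracle)."""
    sop = iop = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            if dx * dy == 1:
                sop += 1
            elif dx * dy == -1:
                iop += 1
    return sop, iop


class TestRelativeIndex:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([5] * 25, 1.0),
            ([1] * 25, 0.2),
            ([5] * 10 + [4] * 10 + [3] * 5, 0.84),
        ],
    )
    def test_examples(self, values, expected):
        rec = df.relative_index(pd.DataFrame({"c": values}), "c")
        assert rec.ri == pytest.approx(expected)
        assert rec.n == len(values)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=40)
    )
    def test_weighted_sum_oracle_and_bounds(self, values):
        rec = df.relative_index(pd.DataFrame({"c": values}), "c")
        oracle = sum((v / 5) for v in values) / len(values)
        assert rec.ri == pytest.approx(oracle)
        assert 0.2 <= rec.ri <= 1.0
        assert sum(rec.frequencies) == rec.n

    def test_order_invariance_and_monotone_in_top_rating(self):
        values = [3, 5, 2, 4, 4]
        a = df.relative_index(pd.DataFrame({"c": values}), "c")
        b = df.relative_index(pd.DataFrame({"c": values[::-1]}), "c")
        assert a.ri == b.ri
        c = df.relative_index(pd.DataFrame({"c": values + [5]}), "c")
        assert c.ri >= a.ri

    def test_missing_excluded_from_n(self):
        rec = df.relative_index(pd.DataFrame({"c": [5, 5, np.nan]}), "c")
        assert rec.n == 2 and rec.ri == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(InsufficientDataError):
            df.relative_index(pd.DataFrame({"c": [np.nan]}), "c")


class TestRankAndClassify:
    def test_singleton_fundamental(self):
        out = df.rank_and_classify({"c": 1.0})
        assert out.loc["c", "rank"] == 1
        assert out.loc["c", "subclass"] == "Fundamental"

    def test_tie_broken_by_id(self):
        out = df.rank_and_classify({"b": 0.75, "a": 0.75, "c": 0.9})
        assert list(out.index) == ["c", "a", "b"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_subclass_boundaries(self):
        out = df.rank_and_classify(
            {"f": 0.8, "i": 0.7, "r": 0.699}, cutpoints=(0.8, 0.7)
        )
        assert out.loc["f", "subclass"] == "Fundamental"
        assert out.loc["i", "subclass"] == "Important"
        assert out.loc["r", "subclass"] == "Relevant"

    def test_inverted_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            df.rank_and_classify({"a": 0.5}, cutpoints=(0.7, 0.8))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            df.rank_and_classify({})


class TestGamma:
    @pytest.mark.parametrize(
        "x,y,sop,iop,g",
        [
            ([1, 2, 3], [1, 2, 3], 3, 0, 1.0),
            ([1, 2, 3], [3, 2, 1], 0, 3, -1.0),
            ([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], 9, 1, 0.8),
        ],
    )
    def test_examples(self, x, y, sop, iop, g):
        res = df.gamma(x, y)
        assert (res.sop, res.iop) == (sop, iop)
        assert res.gamma == pytest.approx(g)

    def test_all_ties_flagged_undefined(self):
        res = df.gamma([2, 2, 2], [1, 3, 5])
        assert res.undefined and res.gamma is None and not res.strong

    @settings(derandomize=True, max_examples=300)
    @given(
        st.integers(min_value=2, max_value=12).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(1, 5), min_size=n, max_size=n),
                st.lists(st.integers(1, 5), min_size=n, max_size=n),
            )
        )
    )
    def test_pair_counts_match_naive_oracle(self, xy):
        x, y = xy
        assert _pair_counts(np.array(x, float), np.array(y, float)) == \
            naive_pair_counts(x, y)

    def test_symmetry_relabelling_and_reversal(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 6, 40).astype(float)
        y = rng.integers(1, 6, 40).astype(float)
        g_xy = df.gamma(x, y).gamma
        assert df.gamma(y, x).gamma == pytest.approx(g_xy)
        relabel = np.array([0, 1, 2, 5, 8, 9])  # increasing map of 1..5
        assert df.gamma(relabel[x.astype(int)], y).gamma == pytest.approx(g_xy)
        assert df.gamma(6 - x, y).gamma == pytest.approx(-g_xy)

    def test_perfect_association_p_value_finite(self):
        res = df.gamma([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.gamma == 1.0
        assert 0.0 <= res.p_value < 0.05

    def test_exact_permutation_p_for_distinct_concordant_vectors(self):
        # with 7 distinct values only the identity and the full reversal of
        # the 7! orderings reach |gamma| = 1, so the exact p is 2/5040
        x = [1, 2, 3, 4, 5, 6, 7]
        res = df.gamma(x, x, p_method="permutation")
        assert res.gamma == 1.0
        assert res.p_value == pytest.approx(2 / 5040)

    def test_strong_requires_both_conditions(self):
        # |gamma| > 0.5 but n = 4: the z-test cannot reach significance
        res = df.gamma([1, 2, 3, 4], [2, 1, 3, 4])
        assert res.gamma == pytest.approx(2 / 3)
        assert res.p_value >= 0.05
        assert not res.strong


class TestDomainScreen:
    def test_correlated_domain_all_strong_positive(self, codebook):
        spec = df.study_panel_spec(codebook, seed=21)
        spec.n_panellists = 200
        spec.within_domain_rho = {d: 0.8 for d, _ in spec.domains}
        spec.contamination = {}
        spec.dnk_rate = 0.0
        table = df.generate_responses(spec)
        screen = df.GammaScreen(codebook).fit(table)
        htm = screen.table_.query("criterion_a.str.startswith('2.')")
        assert htm["strong"].all()
        assert (htm["sign"] == "+").all()

    def test_independent_criteria_rarely_strong(self, codebook):
        spec = df.study_panel_spec(codebook, seed=22)
        spec.n_panellists = 200
        spec.within_domain_rho = {d: 0.0 for d, _ in spec.domains}
        spec.contamination = {}
        spec.dnk_rate = 0.0
        table = df.generate_responses(spec)
        screen = df.GammaScreen(codebook).fit(table)
        assert screen.table_["strong"].mean() <= 0.05

    def test_only_within_domain_pairs(self, codebook, study_spec):
        table = df.generate_responses(study_spec)
        screen = df.GammaScreen(codebook).fit(table)
        for res in screen.results_:
            a, b = res.pair
            assert codebook.domain_of(a) == codebook.domain_of(b)
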