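from fractions import Fraction
from math import comb

import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm.enrich import (
    GeneSetLibrary,
    bh_adjust,
    ora,
    read_gmt,
    rows_to_frame,
    tf_nes,
    top_terms,
    write_gmt,
)
from netpharm.errors import EmptyQueryError, ValidationError
from netpharm.targets import GeneSet

from _oracles import brute_bh, exact_hypergeom_tail


def genes(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


def library(terms, universe=None):
    return GeneSetLibrary(
        "lib",
        {t: frozenset(gs) for t, gs in terms.items()},
        frozenset(universe) if universe else frozenset(),
    )


def query(*members):
    return GeneSet("query", frozenset(members))


class TestGeneSetLibrary:
    def test_universe_defaults_to_term_union(self):
        lib = library({"T1": ["A", "B"], "T2": ["B", "C"]})
        assert lib.universe == {"A", "B", "C"}

    def test_term_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            library({"T1": ["A", "Z"]}, universe=["A", "B"])

    def test_empty_term_rejected(self):
        with pytest.raises(ValidationError):
            library({"T1": []})

    def test_background_padding(self):
        lib = library({"T1": ["A", "B"]}).with_background(100)
        assert len(lib.universe) == 100
        with pytest.raises(ValidationError):
            lib.with_background(1)


class TestORA:
    def test_full_overlap_closed_form(self):
        uni = genes("G", 100)
        term = uni[:10]
        lib = library({"T": term}, universe=uni)
        rows = ora(query(*term), lib)
        assert rows[0].p == pytest.approx(1 / comb(100, 10))

    def test_zero_overlap_convention(self):
        uni = genes("G", 100)
        lib = library({"T": uni[:10]}, universe=uni)
        rows = ora(query(*uni[50:60]), lib)
        assert rows[0].p == 1.0
        assert rows[0].odds_ratio == 0.0

    def test_odds_ratio_contingency(self):
        uni = genes("G", 100)
        lib = library({"T": uni[:10]}, universe=uni)
        rows = ora(query(*uni[5:15]), lib)  # k=5, K=10, n=10, N=100
        assert rows[0].k == 5
        assert rows[0].odds_ratio == pytest.approx((5 * 85) / (5 * 5))

    def test_infinite_odds_ratio_when_term_consumed(self):
        uni = genes("G", 100)
        lib = library({"T": uni[:10]}, universe=uni)
        rows = ora(query(*uni[:10]), lib)
        assert rows[0].odds_ratio == float("inf")

    def test_family_size_includes_zero_overlap_terms(self):
        uni = genes("G", 50)
        lib = library({"HIT": uni[:5], "MISS1": uni[10:15], "MISS2": uni[20:25]}, universe=uni)
        rows = ora(query(*uni[:5]), lib)
        assert len(rows) == 3  # m = library size, not overlap count

    def test_p_matches_exact_oracle(self):
        uni = genes("G", 40)
        lib = library(
            {"T1": uni[:8], "T2": uni[4:16], "T3": uni[30:35]}, universe=uni
        )
        q = query(*uni[2:12])
        for row in ora(q, lib):
            exact = exact_hypergeom_tail(row.k, row.N, row.K, row.n) if row.k else Fraction(1)
            assert row.p == pytest.approx(float(exact), rel=1e-12)

    def test_rows_ranked_by_q_then_p_then_term(self):
        uni = genes("G", 60)
        lib = library(
            {"B": uni[:10], "A": uni[:10], "C": uni[40:50]}, universe=uni
        )
        rows = ora(query(*uni[:10]), lib)
        assert [r.term for r in rows] == ["A", "B", "C"]
        assert [r.rank for r in rows] == [1, 2, 3]

    def test_empty_effective_query_rejected(self):
        lib = library({"T": ["A", "B"]})
        with pytest.raises(EmptyQueryError):
            ora(query("Z1", "Z2"), lib)

    def test_frame_layout(self):
        uni = genes("G", 30)
        lib = library({"T": uni[:5]}, universe=uni)
        df = rows_to_frame(ora(query(*uni[:5]), lib))
        assert list(df.columns) == [
            "term", "overlap_genes", "k", "K", "n", "N", "p", "q", "odds_ratio", "rank",
        ]


class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value(self):
        assert bh_adjust([1.0]) == [1.0]

    def test_identical_ps_are_fixed_points(self):
        # with m identical p's, min_{j>=i} p*m/j is attained at j=m, so q = p
        assert bh_adjust([0.2] * 4) == pytest.approx([0.2] * 4)
        assert bh_adjust([0.5] * 4) == pytest.approx([0.5] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_empty(self):
        assert bh_adjust([]) == []

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_matches_definition_oracle(self, ps):
        assert bh_adjust(ps) == pytest.approx(brute_bh(ps))


class TestTopTerms:
    def _rows(self):
        uni = genes("G", 60)
        lib = library(
            {
                "STRONG": uni[:10],
                "MEDIUM": uni[5:20],
                "NULL1": uni[40:50],
                "NULL2": uni[45:55],
            },
            universe=uni,
        )
        return ora(query(*uni[:10]), lib)

    def test_top_by_q(self):
        rows = self._rows()
        top = top_terms(rows, by="q", k=2)
        assert [r.term for r in top] == [r.term for r in rows[:2]]

    def test_k_larger_than_rows(self):
        rows = self._rows()
        assert len(top_terms(rows, by="q", k=99)) == len(rows)

    def test_by_odds_ratio_descending(self):
        top = top_terms(self._rows(), by="odds_ratio", k=4)
        ors = [r.odds_ratio for r in top]
        assert ors == sorted(ors, reverse=True)

    def test_bad_key_and_k(self):
        rows = self._rows()
        with pytest.raises(ValidationError):
            top_terms(rows, by="p", k=1)
        with pytest.raises(ValidationError):
            top_terms(rows, by="q", k=0)


class TestTFNES:
    def test_covering_regulon_scores_positive_and_hits_all(self):
        uni = genes("G", 200)
        q = uni[:7]
        lib = library({"COVER": q + uni[50:70], "OTHER": uni[100:130]}, universe=uni)
        rows = tf_nes(query(*q), lib, n_perm=200, seed=0)
        top = rows[0]
        assert top.tf == "COVER"
        assert top.n_targets_hit == 7
        assert top.nes > 0

    def test_disjoint_regulon_nonpositive(self):
        uni = genes("G", 200)
        lib = library({"FAR": uni[100:130], "NEAR": uni[:10]}, universe=uni)
        rows = tf_nes(query(*uni[:7]), lib, n_perm=200, seed=0)
        far = next(r for r in rows if r.tf == "FAR")
        assert far.n_targets_hit == 0
        assert far.nes <= 0

    def test_deterministic_for_seed(self):
        uni = genes("G", 100)
        lib = library({"A": uni[:20], "B": uni[30:60]}, universe=uni)
        q = query(*uni[:10])
        assert tf_nes(q, lib, n_perm=150, seed=7) == tf_nes(q, lib, n_perm=150, seed=7)

    def test_too_few_permutations_rejected(self):
        lib = library({"A": ["X", "Y"]})
        with pytest.raises(ValidationError):
            tf_nes(query("X"), lib, n_perm=10)

    def test_query_outside_universe_rejected(self):
        lib = library({"A": ["X", "Y"]})
        with pytest.raises(EmptyQueryError):
            tf_nes(query("Z"), lib, n_perm=100)


class TestGMT:
    def test_roundtrip(self, tmp_path):
        lib = library({"T1": ["A", "B"], "T2": ["C"]})
        p = tmp_path / "lib.gmt"
        write_gmt(lib, p)
        back = read_gmt(p)
        assert back.terms == lib.terms

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("T1\tdesc\n")
        with pytest.raises(ValidationError):
            read_gmt(p)
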