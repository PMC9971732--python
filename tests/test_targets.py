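import pytest
from hypothesis import given
from hypothesis import strategies as st

from netpharm.errors import LabelClashError, SymbolError, ValidationError
from netpharm.targets import (
    GeneSet,
    aggregate_sources,
    combine_related,
    containment_report,
    normalize_symbols,
    read_alias_map,
    read_gene_list,
    venn,
    venn_summary,
    write_gene_list,
)


def gs(label, *members):
    return GeneSet(label, frozenset(members))


class TestNormalizeSymbols:
    def test_case_and_whitespace_collapse(self):
        result, warnings = normalize_symbols(["agt", "AGT ", "Agt"])
        assert result.members == {"AGT"}
        assert len(result) == 1

    def test_plain_tokens_uppercased(self):
        result, _ = normalize_symbols(["mmp9", "timp1"])
        assert result.members == {"MMP9", "TIMP1"}

    def test_alias_lookup(self):
        result, warnings = normalize_symbols(["P01019"], alias_map={"P01019": "AGT"})
        assert result.members == {"AGT"}
        assert warnings == []

    def test_unmapped_tokens_kept_and_warned(self):
        result, warnings = normalize_symbols(["weird1", "P01019"], alias_map={"P01019": "AGT"})
        assert result.members == {"WEIRD1", "AGT"}
        assert warnings == ["WEIRD1"]

    def test_empty_input_gives_empty_set(self):
        result, warnings = normalize_symbols([])
        assert len(result) == 0
        assert warnings == []

    def test_empty_token_rejected(self):
        with pytest.raises(SymbolError):
            normalize_symbols(["   "])

    def test_internal_whitespace_rejected(self):
        with pytest.raises(SymbolError):
            normalize_symbols(["MMP 9"])

    def test_provenance_records_source(self):
        result, _ = normalize_symbols(["agt"], label="albiglutide", source="sea")
        assert result.provenance["AGT"] == {"sea"}


class TestGeneSet:
    def test_provenance_defaults_to_label(self):
        g = gs("drug", "AGT")
        assert g.provenance["AGT"] == {"drug"}

    def test_provenance_for_non_member_rejected(self):
        with pytest.raises(ValidationError):
            GeneSet("x", frozenset({"A"}), {"B": frozenset({"x"})})

    def test_iteration_is_sorted(self):
        assert list(gs("x", "B", "A", "C")) == ["A", "B", "C"]


class TestAggregateSources:
    def test_union_with_merged_provenance(self):
        agg = aggregate_sources({"A": gs("A", "X", "Y"), "B": gs("B", "Y", "Z")}, "drug")
        assert agg.members == {"X", "Y", "Z"}
        assert agg.provenance["Y"] == {"A", "B"}
        assert agg.provenance["X"] == {"A"}

    def test_single_source_identity(self):
        agg = aggregate_sources({"A": gs("A", "X")}, "drug")
        assert agg.members == {"X"}

    def test_duplicate_source_labels_rejected(self):
        with pytest.raises(LabelClashError):
            aggregate_sources([("A", gs("A", "X")), ("A", gs("A", "Y"))], "drug")

    def test_order_independent(self):
        items = [("A", gs("A", "X", "Y")), ("B", gs("B", "Y"))]
        fwd = aggregate_sources(items, "d")
        rev = aggregate_sources(list(reversed(items)), "d")
        assert fwd.members == rev.members
        assert fwd.provenance == rev.provenance

    def test_idempotent(self):
        agg = aggregate_sources({"A": gs("A", "X", "Y")}, "d")
        again = aggregate_sources({"A": agg.relabel("A")}, "d")
        assert again.members == agg.members


class TestVenn:
    def test_two_set_regions(self):
        res = venn([gs("A", "X", "Y"), gs("B", "Y", "Z")])
        assert res.region_counts == {
            frozenset({"A"}): 1,
            frozenset({"B"}): 1,
            frozenset({"A", "B"}): 1,
        }
        assert res.intersection.members == {"Y"}

    def test_identical_sets(self):
        res = venn([gs("A", "X", "Y"), gs("B", "X", "Y")])
        assert res.intersection.members == {"X", "Y"}
        assert res.region_counts == {frozenset({"A", "B"}): 2}

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValidationError):
            venn([gs("A", "X")])

    def test_more_than_six_sets_rejected(self):
        with pytest.raises(ValidationError):
            venn([gs(f"S{i}", "X") for i in range(7)])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(LabelClashError):
            venn([gs("A", "X"), gs("A", "Y")])

    @given(
        st.lists(
            st.frozensets(st.sampled_from(["G1", "G2", "G3", "G4", "G5", "G6"])),
            min_size=2,
            max_size=4,
        )
    )
    def test_regions_partition_the_union(self, member_sets):
        sets = [GeneSet(f"S{i}", m) for i, m in enumerate(member_sets)]
        res = venn(sets)
        union = frozenset().union(*(s.members for s in sets))
        # counts sum to the union size
        assert sum(res.region_counts.values()) == len(union)
        # regions are pairwise disjoint and each gene's signature is correct
        seen = set()
        for sig, genes in res.regions.items():
            assert not (seen & genes)
            seen |= genes
            for g in genes:
                true_sig = frozenset(s.label for s in sets if g in s.members)
                assert sig == true_sig
        assert seen == union

    def test_summary_is_json_ready(self):
        res = venn([gs("A", "X", "Y"), gs("B", "Y")])
        summary = venn_summary(res)
        assert summary["intersection"] == ["Y"]
        assert {"signature": ["A", "B"], "count": 1} in summary["regions"]


class TestCombineRelated:
    def test_disjoint_sizes_add(self):
        a = gs("inter", *(f"I{i}" for i in range(31)))
        b = gs("assoc", *(f"A{i}" for i in range(20)))
        combined = combine_related(a, b)
        assert len(combined) == 51

    def test_union_with_empty_is_identity(self):
        a = gs("inter", "X", "Y")
        assert combine_related(a, gs("assoc")).members == a.members

    def test_overlapping_inputs(self):
        assert combine_related(gs("a", "X", "Y"), gs("b", "Y")).members == {"X", "Y"}

    def test_commutative(self):
        a, b = gs("a", "X", "Y"), gs("b", "Y", "Z")
        assert combine_related(a, b).members == combine_related(b, a).members

    def test_provenance_merged(self):
        combined = combine_related(gs("a", "Y"), gs("b", "Y"))
        assert combined.provenance["Y"] == {"a", "b"}


class TestContainmentReport:
    def test_subset(self):
        ok, missing = containment_report(gs("i", "X"), gs("o", "X", "Y"))
        assert ok and len(missing) == 0

    def test_not_subset(self):
        ok, missing = containment_report(gs("i", "X", "Z"), gs("o", "X", "Y"))
        assert not ok
        assert missing.members == {"Z"}


class TestIO:
    def test_gene_list_roundtrip_with_comments(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# header\nAGT\n\nMMP9  # trailing comment\n")
        assert read_gene_list(p) == ["AGT", "MMP9"]

    def test_write_gene_list(self, tmp_path):
        p = tmp_path / "out.txt"
        write_gene_list(gs("x", "B", "A"), p)
        assert p.read_text() == "A\nB\n"

    def test_alias_map_reader(self, tmp_path):
        p = tmp_path / "alias.tsv"
        p.write_text("# alias\tsymbol\nP01019\tAGT\n")
        assert read_alias_map(p) == {"P01019": "AGT"}

    def test_alias_map_bad_row_rejected(self, tmp_path):
        p = tmp_path / "alias.tsv"
        p.write_text("P01019\n")
        with pytest.raises(ValidationError):
            read_alias_map(p)
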