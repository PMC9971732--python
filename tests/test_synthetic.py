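import networkx as nx
import pytest

from netpharm.assoc import expand_related
from netpharm.errors import UnsatisfiableSpecError, ValidationError
from netpharm.ppi import drop_isolated, filter_confidence
from netpharm.synthetic import (
    HIGH_CONF,
    TargetSetSpec,
    gen_association,
    gen_library,
    gen_ppi,
    gen_target_sets,
    gen_universe,
    gen_study,
    validate_truth,
    write_study,
)
from netpharm.targets import GeneSet, containment_report, venn


class TestGenUniverse:
    def test_unique_symbols(self):
        uni = gen_universe(5, seed=1)
        assert len(uni) == len(set(uni)) == 5

    def test_deterministic(self):
        assert gen_universe(100, seed=2) == gen_universe(100, seed=2)

    def test_zero_rejected(self):
        with pytest.raises(ValidationError):
            gen_universe(0)


class TestGenTargetSets:
    def test_common_core_region_realized_exactly(self):
        spec = TargetSetSpec.with_common_core({"d1": 77, "d2": 77, "d3": 56}, core=12)
        sets, _ = gen_target_sets(gen_universe(500), spec, seed=4)
        res = venn([sets["d1"], sets["d2"], sets["d3"]])
        assert res.region_counts[frozenset({"d1", "d2", "d3"})] == 12
        assert len(sets["d1"]) == 77 and len(sets["d3"]) == 56

    def test_zero_overlap_means_disjoint(self):
        spec = TargetSetSpec({frozenset({"a"}): 5, frozenset({"b"}): 5})
        sets, _ = gen_target_sets(gen_universe(50), spec, seed=0)
        assert not (sets["a"].members & sets["b"].members)

    def test_nested_spec_yields_containment(self):
        spec = TargetSetSpec.nested("mi", "t2dm", 20, 100)
        sets, _ = gen_target_sets(gen_universe(500), spec, seed=1)
        ok, missing = containment_report(sets["mi"], sets["t2dm"])
        assert ok and len(missing) == 0

    def test_core_larger_than_entity_rejected(self):
        with pytest.raises(UnsatisfiableSpecError):
            TargetSetSpec.with_common_core({"d1": 5}, core=10)

    def test_universe_too_small_rejected(self):
        spec = TargetSetSpec({frozenset({"a"}): 100})
        with pytest.raises(UnsatisfiableSpecError):
            gen_target_sets(gen_universe(10), spec, seed=0)

    def test_deterministic_per_seed(self):
        spec = TargetSetSpec.with_common_core({"a": 10, "b": 10}, core=3)
        uni = gen_universe(100)
        s1, _ = gen_target_sets(uni, spec, seed=9)
        s2, _ = gen_target_sets(uni, spec, seed=9)
        assert {k: v.members for k, v in s1.items()} == {k: v.members for k, v in s2.items()}


class TestGenPPI:
    def test_planted_cliques_survive_the_filter(self):
        g, truth = gen_ppi(n_background=25, planted_modules=(6, 5, 4), seed=2)
        for mod in truth.planted_modules:
            for a in mod:
                for b in mod:
                    if a < b:
                        assert g[a][b]["weight"] >= HIGH_CONF

    def test_hub_attached_to_three_cliques(self):
        g, truth = gen_ppi(
            n_background=25, planted_modules=(6, 5, 4), planted_hubs=2, seed=3
        )
        for h in truth.planted_hubs:
            for mod in truth.planted_modules:
                assert all(g[h][v]["weight"] >= HIGH_CONF for v in mod)

    def test_isolates_drop_out_after_filtering(self):
        g, truth = gen_ppi(
            n_background=20, planted_modules=(4,), seed=5, n_isolates=5
        )
        filtered = drop_isolated(filter_confidence(g, HIGH_CONF))
        assert not (set(filtered.nodes) & set(truth.extras["isolates"]))
        assert filtered.number_of_nodes() == g.number_of_nodes() - 5

    def test_filtered_background_has_no_2core(self):
        g, truth = gen_ppi(n_background=30, planted_modules=(5,), seed=7)
        bg = set(truth.extras["background"])
        hi = nx.Graph(
            (a, b)
            for a, b, d in g.edges(data=True)
            if a in bg and b in bg and d["weight"] >= HIGH_CONF
        )
        assert nx.k_core(hi, 2).number_of_nodes() == 0

    def test_hubs_without_enough_cliques_rejected(self):
        with pytest.raises(UnsatisfiableSpecError):
            gen_ppi(n_background=10, planted_modules=(4, 3), planted_hubs=1, seed=0)

    def test_background_p_zero_gives_tree_background(self):
        # the background is never edgeless: a high-confidence spanning tree
        # keeps the filtered graph connected (documented deviation from a
        # bare Erdos-Renyi background)
        g, truth = gen_ppi(n_background=10, seed=1, background_p=0.0)
        assert g.number_of_edges() == 9
        assert nx.is_tree(g)

    def test_deterministic_per_seed(self):
        g1, _ = gen_ppi(n_background=20, planted_modules=(5, 4), planted_hubs=0, seed=6)
        g2, _ = gen_ppi(n_background=20, planted_modules=(5, 4), planted_hubs=0, seed=6)
        assert set(g1.edges) == set(g2.edges)
        assert all(g1[a][b]["weight"] == g2[a][b]["weight"] for a, b in g1.edges)


class TestGenAssociation:
    def test_planted_associates_recovered_exactly(self):
        seeds = [f"S{i:02d}" for i in range(31)]
        bg = [f"B{i:02d}" for i in range(50)]
        net, truth = gen_association(seeds, 20, bg, seed=4)
        out = expand_related(net, GeneSet("seeds", frozenset(seeds)), k=20)
        assert out.members == truth.planted_associates

    def test_seed_overlap_rejected(self):
        with pytest.raises(UnsatisfiableSpecError):
            gen_association(["S1", "S2", "S3"], 1, ["S1"], seed=0)

    def test_too_many_links_rejected(self):
        with pytest.raises(UnsatisfiableSpecError):
            gen_association(["S1", "S2"], 1, [], seed=0, links_per_associate=3)


class TestGenLibrary:
    def test_fixed_term_size(self):
        lib, _ = gen_library(gen_universe(200), 10, (5, 5), seed=1)
        assert all(len(gs) == 5 for gs in lib.terms.values())

    def test_planted_term_padded(self):
        uni = gen_universe(200)
        lib, truth = gen_library(
            uni, 5, (5, 10), planted=[("PLANTED", uni[:4])], seed=2, pad_planted_to=12
        )
        assert truth.enriched_terms == ["PLANTED"]
        assert set(uni[:4]) <= lib.terms["PLANTED"]
        assert len(lib.terms["PLANTED"]) == 12

    def test_planted_gene_outside_universe_rejected(self):
        with pytest.raises(UnsatisfiableSpecError):
            gen_library(gen_universe(10), 2, (2, 3), planted=[("P", ["NOPE"])], seed=0)


class TestStudy:
    def test_truth_validator_passes(self, demo_study):
        assert validate_truth(demo_study) == []

    def test_headline_counts(self, demo_study):
        t = demo_study.truth
        assert len(t.planted_intersection) == 31
        assert len(t.planted_associates) == 20
        assert len(t.extras["related"]) == 51
        assert len(t.common_core) == 12
        drug_union = frozenset().union(*(s.members for s in demo_study.drugs.values()))
        assert len(drug_union) == 198
        assert len(demo_study.diseases["T2DM"]) == 4623
        assert len(demo_study.diseases["MI"]) == 511

    def test_deterministic(self):
        a, b = gen_study(3), gen_study(3)
        assert a.truth.to_json() == b.truth.to_json()
        assert set(a.ppi_graph.edges) == set(b.ppi_graph.edges)

    def test_write_study_manifest_files_exist(self, demo_study, tmp_path):
        manifest = write_study(demo_study, tmp_path)
        for d, sources in manifest["drug_sources"].items():
            for rel in sources.values():
                assert (tmp_path / rel).is_file()
        for key in ("association_network", "ppi_network", "tf_library", "truth"):
            assert (tmp_path / manifest[key]).is_file()
        for rel in manifest["libraries"].values():
            assert (tmp_path / rel).is_file()
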