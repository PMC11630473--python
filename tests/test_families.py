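"""Protein families (MCL), marker collections, core/variable loci, defense."""

import networkx as nx
import pytest

from prophagekit import (
    GeneFamily,
    MCLParams,
    build_similarity_graph,
    collect_marker_families,
    extract_variable_loci,
    family_frequencies,
    flag_defense,
    generate_phage_cluster,
    mcl_cluster,
)


class TestSimilarityGraph:
    @pytest.mark.parametrize(
        "evalue,weight",
        [(1e-250, 200), (1e-5, 5), (3e-8, 8), (0.0, 200), (1e-300, 200)],
    )
    def test_weight_transform(self, evalue, weight):
        g = build_similarity_graph([("a", "b", evalue)])
        assert g["a"]["b"]["weight"] == weight

    def test_reciprocal_hits_collapse_to_max(self):
        g = build_similarity_graph([("a", "b", 1e-5), ("b", "a", 1e-20)])
        assert g["a"]["b"]["weight"] == 20

    def test_self_hits_dropped(self):
        g = build_similarity_graph([("a", "a", 1e-50)])
        assert g.number_of_edges() == 0 and "a" in g


def _clique(g, nodes, w=1.0):
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            g.add_edge(a, b, weight=w)


class TestMCL:
    def test_disconnected_components_never_merged(self):
        g = nx.Graph()
        _clique(g, ["a1", "a2", "a3"])
        _clique(g, ["b1", "b2", "b3"])
        fams = mcl_cluster(g)
        members = sorted(sorted(f.members) for f in fams)
        assert members == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("lonely")
        _clique(g, ["x", "y", "z"])
        fams = mcl_cluster(g)
        assert ["lonely"] in [f.members for f in fams]

    def test_barbell_splits_at_bridge(self):
        """Two 4-cliques joined by one edge separate at inflation 3."""
        g = nx.Graph()
        _clique(g, [0, 1, 2, 3])
        _clique(g, [4, 5, 6, 7])
        g.add_edge(3, 4, weight=1.0)
        fams = mcl_cluster(g)
        members = sorted(sorted(f.members) for f in fams)
        assert members == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_output_is_partition(self):
        g = nx.erdos_renyi_graph(40, 0.15, seed=5)
        nx.set_edge_attributes(g, 1.0, "weight")
        fams = mcl_cluster(g)
        seen = [m for f in fams for m in f.members]
        assert sorted(seen) == sorted(g.nodes)
        assert len(seen) == len(set(seen))

    def test_refines_connected_components(self):
        g = nx.erdos_renyi_graph(30, 0.1, seed=6)
        nx.set_edge_attributes(g, 1.0, "weight")
        fams = mcl_cluster(g)
        comp_of = {}
        for i, comp in enumerate(nx.connected_components(g)):
            for n in comp:
                comp_of[n] = i
        for fam in fams:
            assert len({comp_of[m] for m in fam.members}) == 1

    def test_deterministic(self):
        g = nx.erdos_renyi_graph(25, 0.2, seed=7)
        nx.set_edge_attributes(g, 2.0, "weight")
        a = [f.members for f in mcl_cluster(g)]
        b = [f.members for f in mcl_cluster(g)]
        assert a == b


class TestMarkerCollections:
    def test_family_members_join_seed_realm(self):
        fams = [GeneFamily("f0", ["p1", "p2", "p3"]), GeneFamily("f1", ["q1"])]
        collections, conflicts = collect_marker_families(fams, {"p1": "tailed"})
        assert collections == {"tailed": ["p1", "p2", "p3"]}
        assert conflicts == []

    def test_conflicting_realms_excluded(self):
        fams = [GeneFamily("f0", ["p1", "p2"])]
        collections, conflicts = collect_marker_families(
            fams, {"p1": "tailed", "p2": "tailless"}
        )
        assert collections == {} and conflicts == ["f0"]


class TestFamilyFrequencies:
    def test_threshold_classes(self):
        members = {f"g{i}": [] for i in range(10)}
        for i in range(9):
            members[f"g{i}"].append("core_like")
        for i in range(3):
            members[f"g{i}"].append("rare")
        for i in range(5):
            members[f"g{i}"].append("middling")
        cluster = family_frequencies("c", members)
        assert cluster.family_class["core_like"] == "core"      # 0.9 > 0.8
        assert cluster.family_class["rare"] == "variable"       # 0.3 <= 0.3
        assert cluster.family_class["middling"] == "intermediate"


class TestVariableLoci:
    def _cluster(self, n=5):
        members = {f"g{i}": ["C1", "C2", "C3"] for i in range(n)}
        members["g0"] = ["C1", "C2", "v1", "v2", "C3"]
        cluster = family_frequencies("c", members)
        ordered = {
            g: [(f"{g}_{j}", fam) for j, fam in enumerate(members[g])]
            for g in members
        }
        return cluster, ordered

    def test_locus_between_core_flanks(self):
        cluster, ordered = self._cluster()
        loci = extract_variable_loci(cluster, ordered)
        assert len(loci) == 1
        locus = loci[0]
        assert (locus.left_core, locus.right_core) == ("C2", "C3")
        assert locus.gene_index_span == (2, 3)
        assert locus.member_genes == ["g0_2", "g0_3"]

    def test_small_clusters_yield_nothing(self):
        cluster, ordered = self._cluster(n=4)
        assert extract_variable_loci(cluster, ordered) == []

    def test_edge_variable_gene_unflanked(self):
        members = {f"g{i}": ["C1", "C2", "C3"] for i in range(5)}
        members["g0"] = ["v1", "C1", "C2", "C3"]
        cluster = family_frequencies("c", members)
        ordered = {
            g: [(f"{g}_{j}", fam) for j, fam in enumerate(members[g])]
            for g in members
        }
        assert extract_variable_loci(cluster, ordered) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_planted_loci_exactly(self, seed):
        tables, truth = generate_phage_cluster(
            n_genomes=8, n_core_families=6, variable_pool_size=30,
            locus_slot=3, variable_genes_per_genome=2, seed=seed,
        )
        members = {g: list(df["family"]) for g, df in tables.items()}
        cluster = family_frequencies("fixture", members)
        ordered = {
            g: list(zip(df["gene_id"], df["family"])) for g, df in tables.items()
        }
        loci = {l.prophage_id: l.gene_index_span for l in
                extract_variable_loci(cluster, ordered)}
        assert loci == {g: tuple(span) for g, span in truth.variable_loci.items()}
        for fam, cls in truth.family_classes.items():
            if fam in cluster.family_class:
                assert cluster.family_class[fam] == cls


class TestDefenseFlag:
    def test_adjacent_toxin_antitoxin_is_complete(self):
        genes = [("g1", ["toxin HigB"]), ("g2", ["antitoxin HigA"])]
        state, systems = flag_defense(genes)
        assert state == "complete_system" and "toxin-antitoxin" in systems

    def test_external_tool_report_is_complete(self):
        state, systems = flag_defense([("g1", ["hypothetical protein"])],
                                      external_complete=True)
        assert state == "complete_system"

    def test_lone_defense_gene_is_incomplete(self):
        state, _ = flag_defense([("g1", ["abortive infection protein"])])
        assert state == "incomplete_system"

    def test_hypotheticals_are_other(self):
        state, _ = flag_defense([("g1", ["hypothetical protein"]),
                                 ("g2", ["hypothetical protein"])])
        assert state == "other"

    def test_rule_table_over_label_grid(self):
        labels = {
            "toxin": "toxin RelE", "antitoxin": "antitoxin RelB",
            "abi": "abortive infection protein", "re": "restriction endonuclease",
            "hp": "hypothetical protein",
        }
        for left in labels:
            for right in labels:
                genes = [("g1", [labels[left]]), ("g2", [labels[right]])]
                state, _ = flag_defense(genes)
                adjacent_ta = {left, right} == {"toxin", "antitoxin"}
                any_defense = {left, right} - {"hp"}
                if adjacent_ta:
                    expected = "complete_system"
                elif any_defense:
                    expected = "incomplete_system"
                else:
                    expected = "other"
                assert state == expected, (left, right)
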