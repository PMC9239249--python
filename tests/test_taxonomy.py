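"""Protein clustering, family/genus assignment rules, cross-family shared
proteins, classification of new contigs, and network export."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from microvinet.records import AlignmentHit, GeneFeature, GenomeRecord
from microvinet.simulate import simulate_taxonomy
from microvinet.taxonomy import (
    SINGLETON, BipartiteNetwork, MicrovirusTaxonomy, ProteinCluster,
    assign_families, assign_genera, cluster_proteins, clusters_nest,
    detect_shared_accessory, export_network, protein_key, reconcile_ranks,
)

from .oracles import components_oracle


def _hit(a, b):
    return AlignmentHit(a, b, 80.0, 0.9, 50.0)


class TestClusterProteins:
    def test_transitive_closure(self):
        clusters = cluster_proteins(["a", "b", "c"], [_hit("a", "b"), _hit("b", "c")], 30)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(["a", "b", "c"])
        assert clusters[0].cluster_id == "t30:a"

    def test_no_edges_all_singletons(self):
        clusters = cluster_proteins(["a", "b", "c"], [], 30)
        assert len(clusters) == 3
        assert all(len(c.members) == 1 for c in clusters)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(int(rng.integers(3, 13)))]
        edges = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < 0.25:
                    edges.append((nodes[i], nodes[j]))
        clusters = cluster_proteins(nodes, [_hit(u, v) for u, v in edges], 30)
        assert sorted((c.members for c in clusters), key=min) == components_oracle(nodes, edges)

    def test_majority_hallmark_label(self):
        labels = {"a": "VP1", "b": "VP1", "c": "unknown"}
        clusters = cluster_proteins(["a", "b", "c"], [_hit("a", "b"), _hit("b", "c")], 30, labels)
        assert clusters[0].hallmark_label == "VP1"

    def test_tier_nesting_on_planted_model(self, planted_full):
        model = planted_full["model"]
        assert clusters_nest(model.clusters50_, model.clusters30_)


def _mini_genome(gid, labels, start0=0):
    genes = [
        GeneFeature(f"g{i}", start0 + 400 * i, start0 + 400 * i + 303, "+", 11, "M" * 100, lab)
        for i, lab in enumerate(labels)
    ]
    return GenomeRecord(gid, "ACGT" * 1000, True, genes=genes)


class TestAssignFamilies:
    def _clusters(self, members, label="VP1"):
        return ProteinCluster(f"t30:{min(members)}", 30, frozenset(members), label)

    def test_vp1_cluster_members_share_family(self):
        genomes = [_mini_genome(f"g{i}", ["VP1", "VP2", "VP4"]) for i in range(3)]
        keys = [protein_key(g.genome_id, "g0") for g in genomes]
        clusters = [self._clusters(keys[:2]), self._clusters(keys[2:])]
        modules = {g.genome_id: 0 for g in genomes}
        fam, defining = assign_families(modules, clusters, genomes)
        assert fam["g0"] == fam["g1"]
        assert len(defining) == 1  # the singleton VP1 cluster does not define

    def test_unconnected_vp1_singleton(self):
        genomes = [_mini_genome(f"g{i}", ["VP1", "VP2", "VP4"]) for i in range(3)]
        keys = [protein_key(g.genome_id, "g0") for g in genomes]
        clusters = [self._clusters(keys[:2]), self._clusters(keys[2:])]
        modules = {"g0": 0, "g1": 0, "g2": 1}
        fam, _ = assign_families(modules, clusters, genomes)
        assert fam["g2"] == SINGLETON

    @pytest.mark.parametrize("n,expected_family", [(6, True), (5, False)])
    def test_vp1less_provisional_family_threshold(self, n, expected_family):
        # cohesive VP1-less group: > 5 genomes become a provisional family,
        # 5 or fewer are singletons
        genomes = [_mini_genome(f"g{i}", ["unknown", "VP2", "VP4"]) for i in range(n)]
        modules = {g.genome_id: 0 for g in genomes}
        fam, _ = assign_families(modules, [], genomes)
        if expected_family:
            assert len({fam[g.genome_id] for g in genomes}) == 1
            assert fam["g0"].startswith("PF:")
        else:
            assert all(fam[g.genome_id] == SINGLETON for g in genomes)


class TestAssignGenera:
    def test_near_identical_module_one_genus(self, small_planted):
        genomes, truth = small_planted
        members = [g for g in genomes if truth.genus[g.genome_id] == "fam0g0"]
        modules = {g.genome_id: 0 for g in members}
        genus = assign_genera(modules, members)
        assert len(set(genus.values())) == 1

    def test_permuted_gene_order_member_split(self):
        genomes, truth = simulate_taxonomy(
            n_families=1, genera_per_family=2, genomes_per_genus=2, seed=13,
            order_permutations={"fam0g1": ("VP1", "VP4", "VP2")},
        )
        modules = {g.genome_id: 0 for g in genomes}  # force one module
        genus = assign_genera(modules, genomes)
        g0 = {genus[g] for g in truth.genus if truth.genus[g] == "fam0g0"}
        g1 = {genus[g] for g in truth.genus if truth.genus[g] == "fam0g1"}
        assert not (g0 & g1)

    def test_planted_three_genera_recovered(self, small_planted):
        genomes, truth = small_planted
        model = MicrovirusTaxonomy(seed=0).fit(genomes)
        pred = {a.genome_id: a.genus_id for a in model.assignments_}
        by_truth = {}
        for gid, genus in pred.items():
            by_truth.setdefault(truth.genus[gid], set()).add(genus)
        assert all(len(v) == 1 for v in by_truth.values())
        assert len({min(v) for v in by_truth.values()}) == len(by_truth)


class TestRankReconciliation:
    def test_genus_spanning_families_is_split(self):
        fam = {"a": "F1", "b": "F1", "c": "F2"}
        genus = {"a": "g:a", "b": "g:a", "c": "g:a"}
        out = reconcile_ranks(fam, genus)
        assert out["a"] == out["b"]
        assert out["c"] != out["a"]

    def test_genus_refines_family_on_planted_model(self, planted_full):
        model = planted_full["model"]
        fam_of_genus = {}
        for a in model.assignments_:
            fam_of_genus.setdefault(a.genus_id, set()).add(a.family_id)
        assert all(len(v) == 1 for v in fam_of_genus.values())


class TestSharedAccessory:
    def test_no_cross_family_clusters_empty_report(self, small_planted):
        genomes, _ = small_planted
        model = MicrovirusTaxonomy(seed=0).fit(genomes)
        df = model.shared_accessory_
        assert len(df) == 0

    def test_planted_shared_peptidase_reported(self):
        genomes, truth = simulate_taxonomy(
            n_families=2, genera_per_family=2, genomes_per_genus=2, seed=17,
            shared_accessory=[(0, 1)],
        )
        model = MicrovirusTaxonomy(seed=0).fit(genomes)
        df = model.shared_accessory_
        assert len(df) == 1
        assert df.iloc[0]["n_families"] == 2
        assert "peptidase" in df.iloc[0]["label"]
        # while the families' VP1 proteins stay unrelated (two families kept)
        fams = {a.family_id for a in model.assignments_ if not a.is_singleton}
        assert len(fams) == 2

    def test_report_rows_equal_bruteforce_recount(self):
        genomes, truth = simulate_taxonomy(
            n_families=2, genera_per_family=2, genomes_per_genus=2, seed=17,
            shared_accessory=[(0, 1)],
        )
        model = MicrovirusTaxonomy(seed=0).fit(genomes)
        fam = {a.genome_id: a.family_id for a in model.assignments_}
        expected = 0
        for c in model.clusters30_:
            fams = {fam[g] for g in c.genomes if fam[g] != SINGLETON}
            if len(fams) >= 2:
                expected += 1
        assert len(model.shared_accessory_) == expected


@pytest.fixture(scope="module")
def reference(small_planted):
    genomes, truth = small_planted
    return MicrovirusTaxonomy(seed=0).fit(genomes), genomes, truth


class TestClassifyNew:
    def test_identical_contig_inherits_assignment(self, reference):
        model, genomes, truth = reference
        src = genomes[0]
        clone = GenomeRecord(
            "contig_clone", src.sequence, True,
            genes=[GeneFeature(x.gene_id, x.start, x.end, x.strand, 11, x.protein, x.label) for x in src.genes],
        )
        out = model.predict([clone])
        ref = next(a for a in model.assignments_ if a.genome_id == src.genome_id)
        assert out[0].family_id == ref.family_id
        assert out[0].genus_id == ref.genus_id
        assert out[0].novel_flag is False

    def test_novel_genus_in_known_family(self, reference):
        model, genomes, truth = reference
        # generate a third genus of fam-like divergence by re-simulating the
        # same family seed with more genera and holding the extras out
        big, big_truth = simulate_taxonomy(
            n_families=3, genera_per_family=3, genomes_per_genus=2, seed=7
        )
        held_out = [g for g in big if big_truth.genus[g.genome_id] == "fam0g2"][:1]
        contig = GenomeRecord(
            "contig_novel", held_out[0].sequence, True,
            genes=[GeneFeature(x.gene_id, x.start, x.end, x.strand, 11, x.protein, x.label)
                   for x in held_out[0].genes],
        )
        out = model.predict([contig])
        ref_fam0 = {
            a.family_id for a in model.assignments_
            if truth.family[a.genome_id] == "fam0"
        }
        assert out[0].family_id in ref_fam0
        assert out[0].novel_flag is True

    def test_random_contig_singleton(self, reference, rng):
        model, _, _ = reference
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        contig = GenomeRecord(
            "contig_rand", seq, True,
            genes=[GeneFeature("g0", 0, 303, "+", 11, "M" * 100, "unknown")],
        )
        out = model.predict([contig])
        assert out[0].family_id == SINGLETON


class TestExportNetwork:
    def test_small_network_counts_and_round_trip(self, tmp_path):
        genomes = [_mini_genome("gA", ["VP1"]), _mini_genome("gB", ["VP1"])]
        cluster = ProteinCluster(
            "t30:gA|g0", 30, frozenset([protein_key("gA", "g0"), protein_key("gB", "g0")]), "VP1",
        )
        net = BipartiteNetwork.build(genomes, [cluster], 30)
        from microvinet.records import TaxonAssignment

        assigns = [TaxonAssignment("gA", "F1", "g:gA"), TaxonAssignment("gB", "F1", "g:gA")]
        gml = tmp_path / "net.graphml"
        tsv = tmp_path / "edges.tsv"
        export_network(net, assigns, gml, tsv)
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == 3  # 2 groups + 1 cluster
        assert back.number_of_edges() == 2
        assert sorted(nx.get_node_attributes(back, "kind").values()) == [
            "genome_group", "genome_group", "protein_cluster"
        ]
        lines = tsv.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 edges

    def test_round_trip_topology_of_planted_network(self, tmp_path, planted_full):
        model = planted_full["model"]
        gml = tmp_path / "t30.graphml"
        export_network(model.net30_, model.assignments_, gml)
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == model.net30_.graph.number_of_nodes()
        assert back.number_of_edges() == model.net30_.graph.number_of_edges()
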