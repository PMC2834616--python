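import numpy as np
import pytest

from mirtfnet.network import (
    EDGE_MIRNA_GENE,
    EDGE_TF_GENE,
    EDGE_TF_MIRNA,
    Edge,
    MappedHit,
    TFGroup,
    build_mirna_gene_edges,
    build_tf_edges,
    extract_subnetwork,
    find_core_nodes,
    find_feedback_loops,
    find_ffls,
    find_ffls_bruteforce,
    merge_network,
    merge_tfbs_groups,
)
from mirtfnet.types import (
    Config,
    GenomicInterval,
    MiRNARecord,
    TargetPair,
    TFBSHit,
)


def _mh(matrix, owner, kind, start, consensus="ACGT", symbols=("X",)):
    hit = TFBSHit(matrix, consensus, symbols,
                  GenomicInterval("1", start, start + 20, "+"), 2.5, True)
    return MappedHit(hit, owner, kind)


class TestGroupMerging:
    def test_overlapping_matrices_sharing_symbol_merge(self):
        # three cAMP-response matrices stacked on one promoter
        mapped = [
            _mh("V$CREB_01", "NR4A2", "gene", 100, "TGACGTMA", ("CREB1", "ATF2")),
            _mh("V$CREBP1CJUN_01", "NR4A2", "gene", 105, "TGACGTCA", ("CREB1", "ATF2")),
            _mh("V$CREBP1_Q2", "NR4A2", "gene", 110, "VGTGACGTMACN", ("CREB1", "ATF2")),
        ]
        groups, m2g = merge_tfbs_groups(mapped)
        assert len(groups) == 1
        assert len(set(m2g.values())) == 1

    def test_identical_consensus_merges_without_overlap(self):
        mapped = [
            _mh("V$EGR1_01", "GRIN1", "gene", 100, "TGCGTRGGYGK", ("EGR1",)),
            _mh("V$NGFIC_01", "GRIN1", "gene", 900, "TGCGTRGGYGK", ("EGR3",)),
        ]
        groups, _ = merge_tfbs_groups(mapped)
        (group,) = groups.values()
        assert group.matrix_ids == {"V$EGR1_01", "V$NGFIC_01"}
        assert group.tf_symbols == {"EGR1", "EGR3"}

    def test_disjoint_matrices_stay_separate(self):
        mapped = [
            _mh("V$A_01", "G", "gene", 100, "AAAA", ("A",)),
            _mh("V$B_01", "G", "gene", 900, "BBBB", ("B",)),
        ]
        groups, _ = merge_tfbs_groups(mapped)
        assert len(groups) == 2

    def test_overlap_without_shared_symbol_does_not_merge(self):
        mapped = [
            _mh("V$A_01", "G", "gene", 100, "AAAA", ("A",)),
            _mh("V$B_01", "G", "gene", 105, "BBBB", ("B",)),
        ]
        groups, _ = merge_tfbs_groups(mapped)
        assert len(groups) == 2

    def test_same_matrix_across_promoters_is_one_regulator(self):
        mapped = [
            _mh("V$A_01", "G1", "gene", 100, "AAAA", ("A",)),
            _mh("V$A_01", "G2", "gene", 100, "AAAA", ("A",)),
        ]
        groups, _ = merge_tfbs_groups(mapped)
        assert len(groups) == 1
        tf_gene, _ = build_tf_edges(mapped, {"V$A_01": "V$A_01"})
        assert {e.target for e in tf_gene} == {"G1", "G2"}


def _mir(pid, cons="V"):
    fam = pid.rsplit("-", 1)[0] if pid[-1].isdigit() and "-" in pid else pid
    return MiRNARecord(pid, fam, (fam,),
                       GenomicInterval("1", 1000, 1100, "+"), "INTERGENIC",
                       "intergenic", cons)


class TestMiRNAGeneEdges:
    def test_family_pair_expands_to_all_precursors(self, cfg):
        mirnas = [_mir("hsa-miR-9-1", "A"), _mir("hsa-miR-9-2", "A"),
                  _mir("hsa-miR-9-3", "A")]
        edges = build_mirna_gene_edges(
            [TargetPair("hsa-miR-9", "DRD2", None, True)], mirnas, cfg
        )
        assert [(e.source, e.target) for e in edges] == [
            ("hsa-miR-9-1", "DRD2"),
            ("hsa-miR-9-2", "DRD2"),
            ("hsa-miR-9-3", "DRD2"),
        ]

    def test_nonconserved_site_dropped_unless_primate_specific(self, cfg):
        pair = lambda m: TargetPair(m, "G", None, False)
        assert build_mirna_gene_edges(
            [pair("hsa-miR-195")], [_mir("hsa-miR-195", "M")], cfg
        ) == []
        edges = build_mirna_gene_edges(
            [pair("hsa-miR-198")], [_mir("hsa-miR-198", "P")], cfg
        )
        assert [(e.source, e.target) for e in edges] == [("hsa-miR-198", "G")]

    def test_unknown_mature_name_raises(self, cfg):
        with pytest.raises(KeyError, match="miR-999"):
            build_mirna_gene_edges(
                [TargetPair("hsa-miR-999", "G", None, True)],
                [_mir("hsa-miR-195", "M")], cfg,
            )


def _simple_groups(*gids):
    return {g: TFGroup(g, frozenset({g}), frozenset({f"TF_{g}"})) for g in gids}


class TestFFLEnumeration:
    def test_toy_triangle(self):
        groups = _simple_groups("g")
        tf_gene = [Edge("g", "G", EDGE_TF_GENE)]
        tf_mirna = [Edge("g", "m", EDGE_TF_MIRNA)]
        mirna_gene = [Edge("m", "G", EDGE_MIRNA_GENE)]
        ffls = find_ffls(tf_gene, tf_mirna, mirna_gene, groups)
        assert len(ffls) == 1
        assert (ffls[0].gene, ffls[0].mirna) == ("G", "m")
        assert find_ffls(tf_gene, tf_mirna, [], groups) == []

    def test_reference_bundle_yields_32(self, reference_network):
        assert len(reference_network["ffls"]) == 32

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gids = [f"g{i}" for i in range(rng.integers(2, 8))]
            ms = [f"m{i}" for i in range(rng.integers(2, 8))]
            ts = [f"t{i}" for i in range(rng.integers(2, 8))]
            groups = _simple_groups(*gids)
            tf_gene = [Edge(g, t, EDGE_TF_GENE) for g in gids for t in ts
                       if rng.random() < 0.4]
            tf_mirna = [Edge(g, m, EDGE_TF_MIRNA) for g in gids for m in ms
                        if rng.random() < 0.4]
            mirna_gene = [Edge(m, t, EDGE_MIRNA_GENE) for m in ms for t in ts
                          if rng.random() < 0.4]
            fast = find_ffls(tf_gene, tf_mirna, mirna_gene, groups)
            slow = find_ffls_bruteforce(tf_gene, tf_mirna, mirna_gene, groups)
            assert [(f.gene, f.mirna, f.tf_group.group_id) for f in fast] == [
                (f.gene, f.mirna, f.tf_group.group_id) for f in slow
            ]

    def test_order_invariance(self, reference_network):
        rng = np.random.default_rng(4)
        tf_gene = list(reference_network["tf_gene"])
        tf_mirna = list(reference_network["tf_mirna"])
        mirna_gene = list(reference_network["bundle"].mirna_gene_edges)
        for edges in (tf_gene, tf_mirna, mirna_gene):
            rng.shuffle(edges)
        assert find_ffls(
            tf_gene, tf_mirna, mirna_gene, reference_network["groups"]
        ) == reference_network["ffls"]

    def test_merging_never_increases_ffl_count(self, reference_network):
        """With merging disabled (every matrix its own group) the motif
        count can only grow: merged rows collapse to one loop."""
        bundle = reference_network["bundle"]
        matrix_ids = {mh.hit.matrix_id for mh in bundle.mapped_hits}
        identity = {m: m for m in matrix_ids}
        groups = {
            m: TFGroup(m, frozenset({m}), frozenset()) for m in matrix_ids
        }
        tf_gene, tf_mirna = build_tf_edges(bundle.mapped_hits, identity)
        unmerged = find_ffls(tf_gene, tf_mirna, bundle.mirna_gene_edges, groups)
        assert len(unmerged) >= len(reference_network["ffls"])
        assert len(unmerged) == 36  # rows 12, 26, 30 carry extra matrices


class TestFeedbackLoops:
    def test_mutual_loop_found(self):
        groups = {"g": TFGroup("g", frozenset({"g"}), frozenset({"ESR1"}))}
        tf_mirna = [Edge("g", "hsa-miR-181b-1", EDGE_TF_MIRNA)]
        hit = find_feedback_loops(
            tf_mirna, [Edge("hsa-miR-181b-1", "ESR1", EDGE_MIRNA_GENE)], groups
        )
        assert len(hit) == 1
        assert hit[0].tf_gene_targeted == "ESR1"
        miss = find_feedback_loops(
            tf_mirna, [Edge("hsa-miR-181b-1", "BDNF", EDGE_MIRNA_GENE)], groups
        )
        assert miss == []

    def test_planted_loops_recovered(self, synthetic_bundle):
        # full recovery is exercised end-to-end in the pipeline tests; here
        # the generator's truth table must be internally consistent
        assert len(synthetic_bundle.truth_feedback) == 4


class TestNetworkConvergence:
    def _one_ffl(self):
        groups = _simple_groups("g")
        return find_ffls(
            [Edge("g", "G", EDGE_TF_GENE)],
            [Edge("g", "m", EDGE_TF_MIRNA)],
            [Edge("m", "G", EDGE_MIRNA_GENE)],
            groups,
        )

    def test_disjoint_feedback_loop_excluded(self):
        from mirtfnet.network import FeedbackLoop

        ffls = self._one_ffl()
        stray = FeedbackLoop(
            TFGroup("h", frozenset({"h"}), frozenset({"Y"})), "m2", "Y"
        )
        net = merge_network(ffls, [stray])
        assert set(net.graph.nodes) == {"g", "m", "G"}

    def test_shared_mirna_feedback_loop_included(self):
        from mirtfnet.network import FeedbackLoop

        ffls = self._one_ffl()
        linked = FeedbackLoop(
            TFGroup("h", frozenset({"h"}), frozenset({"Y"})), "m", "Y"
        )
        net = merge_network(ffls, [linked])
        assert "h" in net.graph.nodes
        assert net.graph.number_of_nodes() >= 4

    def test_reference_network_node_classes(self, reference_network):
        net = reference_network["net"]
        assert len(net.nodes_of_kind("gene")) == 16
        assert len(net.nodes_of_kind("mirna")) == 11


class TestCoreNodes:
    def test_reference_core_nodes(self, reference_network, cfg):
        core = find_core_nodes(reference_network["net"], cfg)
        assert core["core_genes"] == ["EGR3", "GRM7"]
        assert core["core_mirnas"] == [
            "hsa-miR-195", "hsa-miR-20b", "hsa-miR-9-3"
        ]

    def test_single_ffl_network_has_no_core(self, cfg):
        groups = _simple_groups("g")
        ffls = find_ffls(
            [Edge("g", "G", EDGE_TF_GENE)],
            [Edge("g", "m", EDGE_TF_MIRNA)],
            [Edge("m", "G", EDGE_MIRNA_GENE)],
            groups,
        )
        core = find_core_nodes(merge_network(ffls), cfg)
        assert core == {"core_genes": [], "core_mirnas": []}

    def test_self_edge_policy_on_egr_group(self, reference_network):
        """The EGR regulator group sits in its own gene's promoter; with
        self-edges excluded it regulates exactly 3 genes and 3 miRNAs."""
        net = reference_network["net"]
        (egr_id,) = [
            gid for gid, g in net.groups.items() if "EGR3" in g.tf_symbols
        ]
        out_genes = net.successors_of_kind(egr_id, "gene",
                                           include_self_edges=False)
        assert out_genes == {"GRIN1", "GRM7", "YWHAH"}
        assert net.successors_of_kind(egr_id, "gene") == out_genes | {"EGR3"}
        assert len(net.successors_of_kind(egr_id, "mirna")) == 3


class TestSubnetworks:
    def test_hub_with_three_neighbors(self):
        groups = _simple_groups("g")
        ffls = find_ffls(
            [Edge("g", "G", EDGE_TF_GENE)],
            [Edge("g", "m", EDGE_TF_MIRNA)],
            [Edge("m", "G", EDGE_MIRNA_GENE)],
            groups,
        )
        net = merge_network(ffls)
        sub = extract_subnetwork(net, "G")
        assert sub.graph.number_of_nodes() == 3

    def test_mir195_subnetwork_gene_neighbors(self, reference_network):
        sub = extract_subnetwork(reference_network["net"], "hsa-miR-195")
        assert len(sub.nodes_of_kind("gene")) == 6

    def test_unknown_node_raises(self, reference_network):
        with pytest.raises(KeyError):
            extract_subnetwork(reference_network["net"], "nope")
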