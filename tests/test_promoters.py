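import numpy as np
import pytest

from mirtfnet.promoters import (
    UnresolvedHostError,
    assign_gene_promoter,
    assign_mirna_promoters,
    cluster_mirnas,
    map_tfbs_bruteforce,
    map_tfbs_to_promoters,
    PromoterAssignment,
)
from mirtfnet.types import (
    Config,
    GenomicInterval,
    GeneRecord,
    MiRNARecord,
    TFBSHit,
)


def _mir(pid, chrom, start, end, strand="+", host="INTERGENIC",
         rel="intergenic", cons="V"):
    return MiRNARecord(pid, pid, (pid,), GenomicInterval(chrom, start, end, strand),
                       host, rel, cons)


def _index(mirnas):
    return {m.precursor_id: m for m in mirnas}


class TestClustering:
    def test_mir29c_and_29b2_form_one_cluster(self, fixtures, cfg):
        idx = _index(fixtures.mirnas)
        clusters = cluster_mirnas(
            [idx["hsa-miR-29c"], idx["hsa-miR-29b-2"]], cfg
        )
        assert len(clusters) == 1
        assert clusters[0].members == ("hsa-miR-29c", "hsa-miR-29b-2")

    def test_isolated_precursor_is_singleton(self, fixtures, cfg):
        idx = _index(fixtures.mirnas)
        (cluster,) = cluster_mirnas([idx["hsa-miR-195"]], cfg)
        assert cluster.members == ("hsa-miR-195",)

    def test_reference_annotation_clusters(self, fixtures, cfg):
        """Exhaustive 5-kb gap chaining over the 29 reference precursors.

        Four pairs are within 5 kb of a same-strand neighbour (verified by
        all-pairs gap arithmetic on the annotated coordinates).
        """
        clusters = cluster_mirnas(list(fixtures.mirnas), cfg)
        multi = sorted(c.members for c in clusters if len(c.members) > 1)
        assert multi == [
            ("hsa-miR-29a", "hsa-miR-29b-1"),
            ("hsa-miR-29c", "hsa-miR-29b-2"),
            ("hsa-miR-30b", "hsa-miR-30d"),
            ("hsa-miR-92a-2", "hsa-miR-20b"),
        ]
        # partition property
        assert sorted(p for c in clusters for p in c.members) == sorted(
            m.precursor_id for m in fixtures.mirnas
        )

    def test_order_independence(self, fixtures, cfg):
        rng = np.random.default_rng(0)
        base = cluster_mirnas(list(fixtures.mirnas), cfg)
        for _ in range(5):
            shuffled = list(fixtures.mirnas)
            rng.shuffle(shuffled)
            assert cluster_mirnas(shuffled, cfg) == base

    def test_gap_just_over_limit_splits(self, cfg):
        a = _mir("a", "1", 1000, 1100)
        b = _mir("b", "1", 1100 + cfg.cluster_max_gap + 1, 7000 + cfg.cluster_max_gap)
        assert len(cluster_mirnas([a, b], cfg)) == 2
        c = _mir("c", "1", 1100 + cfg.cluster_max_gap, 7000 + cfg.cluster_max_gap)
        assert len(cluster_mirnas([a, c], cfg)) == 1

    def test_strand_requirement_is_configurable(self):
        a = _mir("a", "1", 1000, 1100, "+")
        b = _mir("b", "1", 1500, 1600, "-")
        assert len(cluster_mirnas([a, b], Config())) == 2
        assert len(cluster_mirnas([a, b], Config(cluster_same_strand=False))) == 1


class TestPromoterAssignment:
    def test_intergenic_minus_strand_window(self, fixtures, cfg):
        """Upstream of a minus-strand feature is coordinate-increasing."""
        idx = _index(fixtures.mirnas)
        (pa,) = assign_mirna_promoters([idx["hsa-miR-195"]], [], cfg)
        assert pa.basis == "precursor"
        # 1-based display: 17:6861745-6866744
        assert pa.interval.to_one_based() == ("17", 6861745, 6866744, "-")

    def test_genic_mirna_uses_host_gene_promoter(self, fixtures, cfg):
        idx = _index(fixtures.mirnas)
        host = GeneRecord("WDR82", GenomicInterval("3", 52270000, 52290000, "+"))
        (pa,) = assign_mirna_promoters([idx["hsa-let-7g"]], [host], cfg)
        assert pa.basis == "host_gene"
        assert pa.interval == GenomicInterval("3", 52265000, 52270000, "+")

    def test_missing_host_gene_raises(self, fixtures, cfg):
        idx = _index(fixtures.mirnas)
        with pytest.raises(UnresolvedHostError, match="WDR82"):
            assign_mirna_promoters([idx["hsa-let-7g"]], [], cfg)

    def test_antisense_host_treated_as_intergenic(self, fixtures, cfg):
        idx = _index(fixtures.mirnas)
        (pa,) = assign_mirna_promoters([idx["hsa-miR-29a"]], [], cfg)
        assert pa.basis == "precursor"

    def test_cluster_members_share_one_window(self, fixtures, cfg):
        idx = _index(fixtures.mirnas)
        pas = assign_mirna_promoters(
            [idx["hsa-miR-29c"], idx["hsa-miR-29b-2"]], [], cfg
        )
        assert {pa.basis for pa in pas} == {"cluster"}
        assert len({pa.interval for pa in pas}) == 1
        # upstream of the 2-member span on the minus strand
        assert pas[0].interval.start == idx["hsa-miR-29b-2"].interval.end

    def test_gene_promoter_windows(self, cfg):
        plus = GeneRecord("A", GenomicInterval("1", 100000, 120000, "+"))
        assert assign_gene_promoter(plus, cfg).interval == GenomicInterval(
            "1", 95000, 100000, "+"
        )
        minus = GeneRecord("B", GenomicInterval("1", 100000, 120000, "-"))
        assert assign_gene_promoter(minus, cfg).interval == GenomicInterval(
            "1", 120000, 125000, "-"
        )
        short = Config(gene_promoter_len=1000)
        assert assign_gene_promoter(plus, short).interval.length == 1000

    def test_truncation_at_chromosome_start_warns(self):
        gene = GeneRecord("C", GenomicInterval("1", 3000, 9000, "+"))
        with pytest.warns(UserWarning, match="truncated"):
            pa = assign_gene_promoter(gene, Config())
        assert pa.interval == GenomicInterval("1", 0, 3000, "+")

    def test_promoter_never_overlaps_basis_body(self, fixtures, cfg):
        genes = [
            GeneRecord(sym, GenomicInterval("3", 52270000, 52290000, "+"))
            for sym in ("WDR82", "MCM7", "C9orf3", "CTDSP1", "C6orf155",
                        "NFYC", "HNRNPK", "C19orf30", "C1orf61", "FSTL1")
        ]
        idx = _index(fixtures.mirnas)
        for pa in assign_mirna_promoters(list(fixtures.mirnas), genes, cfg):
            if pa.basis == "precursor":
                assert not pa.interval.overlaps(idx[pa.owner].interval)
            assert pa.interval.length == cfg.mirna_promoter_len


def _promoters_for(intervals):
    return [
        PromoterAssignment(f"g{i}", iv, "gene_tss", "gene")
        for i, iv in enumerate(intervals)
    ]


def _hit(matrix, chrom, start, end, z, conserved=True):
    return TFBSHit(matrix, "ACGT", ("X",),
                   GenomicInterval(chrom, start, end, "+"), z, conserved)


class TestTFBSMapping:
    def test_z_cutoff_is_strict(self, cfg):
        promoters = _promoters_for([GenomicInterval("1", 1000, 6000, "+")])
        dropped = map_tfbs_to_promoters([_hit("V$A", "1", 1500, 1510, 2.32)],
                                        promoters, cfg)
        kept = map_tfbs_to_promoters([_hit("V$A", "1", 1500, 1510, 2.34)],
                                     promoters, cfg)
        boundary = map_tfbs_to_promoters([_hit("V$A", "1", 1500, 1510, 2.33)],
                                         promoters, cfg)
        assert dropped == [] and boundary == []
        assert len(kept) == 1

    def test_conservation_filter_configurable(self, cfg):
        promoters = _promoters_for([GenomicInterval("1", 1000, 6000, "+")])
        hit = _hit("V$A", "1", 1500, 1510, 3.0, conserved=False)
        assert map_tfbs_to_promoters([hit], promoters, cfg) == []
        relaxed = Config(require_tfbs_conserved=False)
        assert len(map_tfbs_to_promoters([hit], promoters, relaxed)) == 1

    def test_hit_spanning_two_promoters_yields_two_records(self, cfg):
        promoters = _promoters_for(
            [GenomicInterval("1", 1000, 6000, "+"),
             GenomicInterval("1", 5990, 11000, "+")]
        )
        mapped = map_tfbs_to_promoters([_hit("V$A", "1", 5985, 5995, 3.0)],
                                       promoters, cfg)
        assert sorted(mh.owner for mh in mapped) == ["g0", "g1"]

    def test_raising_cutoff_never_retains_more(self, cfg):
        rng = np.random.default_rng(1)
        promoters = _promoters_for(
            [GenomicInterval("1", int(s), int(s) + 5000, "+")
             for s in rng.integers(0, 10**6, 8)]
        )
        hits = [
            _hit(f"V$H{i}", "1", int(p), int(p) + 12, float(z))
            for i, (p, z) in enumerate(
                zip(rng.integers(0, 10**6, 200), rng.normal(2.3, 0.5, 200))
            )
        ]
        counts = [
            len(map_tfbs_to_promoters(hits, promoters, Config(z_cutoff=z)))
            for z in (1.0, 2.0, 2.33, 3.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_indexed_mapping_equals_all_pairs_scan(self, cfg):
        rng = np.random.default_rng(2)
        promoters = _promoters_for(
            [GenomicInterval(c, int(s), int(s) + 3000, "+")
             for c, s in zip(rng.choice(["1", "2"], 20),
                             rng.integers(0, 10**5, 20))]
        )
        hits = [
            _hit(f"V$H{i}", str(c), int(p), int(p) + 10, float(z), bool(k))
            for i, (c, p, z, k) in enumerate(
                zip(rng.choice(["1", "2", "3"], 50),
                    rng.integers(0, 10**5, 50),
                    rng.normal(2.4, 0.4, 50),
                    rng.integers(0, 2, 50))
            )
        ]
        fast = map_tfbs_to_promoters(hits, promoters, cfg)
        slow = map_tfbs_bruteforce(hits, promoters, cfg)
        key = lambda mh: (mh.hit.matrix_id, mh.owner)
        assert sorted(fast, key=key) == sorted(slow, key=key)
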