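"""miRNA clustering, promoter assignment and TFBS-to-promoter mapping.

Clustered miRNA precursors (inter-precursor gap at most ``cluster_max_gap``,
5 kb by default) are assumed co-transcribed and share one promoter upstream
of the cluster span.  Genic precursors (intronic or 3'UTR-hosted) use their
host gene's promoter; everything else gets a window directly upstream of
the precursor hairpin.  Promoters are fixed-length windows 5' of the basis
feature, computed strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .network import OWNER_GENE, OWNER_MIRNA, MappedHit
from .types import Config, GenomicInterval, GeneRecord, MiRNARecord, TFBSHit

BASIS_HOST_GENE = "host_gene"
BASIS_PRECURSOR = "precursor"
BASIS_CLUSTER = "cluster"
BASIS_GENE_TSS = "gene_tss"


@dataclass(frozen=True)
class MiRNACluster:
    """Precursors on one chromosome chained by gaps <= the cluster limit."""

    members: tuple[str, ...]
    interval: GenomicInterval

    @property
    def cluster_id(self) -> str:
        return "cluster:" + "|".join(self.members)


@dataclass(frozen=True)
class PromoterAssignment:
    """A promoter window owned by a gene symbol or a miRNA precursor."""

    owner: str
    interval: GenomicInterval
    basis: str
    owner_kind: str  # OWNER_GENE / OWNER_MIRNA


class UnresolvedHostError(KeyError):
    """A genic miRNA's host gene is missing from the gene annotation."""


def _gap(prev: GenomicInterval, nxt: GenomicInterval) -> int:
    """Bases strictly between two ordered intervals (half-open arithmetic)."""
    return nxt.start - prev.end


def cluster_mirnas(
    mirnas: Sequence[MiRNARecord], cfg: Config
) -> list[MiRNACluster]:
    """Partition precursors into clusters by single-linkage gap chaining.

    Consecutive precursors (coordinate-sorted per chromosome, and per
    strand when ``cluster_same_strand`` is set) chain into one cluster when
    the gap between them is <= ``cluster_max_gap``.  Singletons come back
    as one-member clusters, so the result is a partition of the input.
    """
    keyed: dict[tuple, list[MiRNARecord]] = {}
    for rec in mirnas:
        key = (rec.interval.chrom, rec.interval.strand) if cfg.cluster_same_strand \
            else (rec.interval.chrom,)
        keyed.setdefault(key, []).append(rec)

    clusters: list[MiRNACluster] = []
    for recs in keyed.values():
        recs = sorted(recs, key=lambda r: (r.interval.start, r.precursor_id))
        run: list[MiRNARecord] = []
        for rec in recs:
            if run and _gap(run[-1].interval, rec.interval) > cfg.cluster_max_gap:
                clusters.append(_make_cluster(run))
                run = []
            run.append(rec)
        if run:
            clusters.append(_make_cluster(run))
    return sorted(clusters, key=lambda c: c.members)


def _make_cluster(run: list[MiRNARecord]) -> MiRNACluster:
    iv = GenomicInterval(
        run[0].interval.chrom,
        min(r.interval.start for r in run),
        max(r.interval.end for r in run),
        run[0].interval.strand,
    )
    return MiRNACluster(tuple(r.precursor_id for r in run), iv)


def _upstream_window(
    basis: GenomicInterval, length: int
) -> GenomicInterval:
    """Fixed-length window immediately 5' of a feature, strand-aware.

    On '+' the window ends at the feature start; on '-' upstream is
    coordinate-increasing, so it begins at the feature end.  Windows that
    would cross coordinate 0 are truncated with a warning.
    """
    if basis.strand == "+":
        start, end = basis.start - length, basis.start
        if start < 0:
            warnings.warn(
                f"promoter window truncated at chromosome start "
                f"({basis.chrom}:{start})"
            )
            start = 0
        if start >= end:
            raise ValueError("feature starts at coordinate 0; no upstream room")
    else:
        start, end = basis.end, basis.end + length
    return GenomicInterval(basis.chrom, start, end, basis.strand)


def assign_gene_promoter(gene: GeneRecord, cfg: Config) -> PromoterAssignment:
    """Promoter of ``gene_promoter_len`` bp ending at the gene's TSS."""
    window = _upstream_window(gene.interval, cfg.gene_promoter_len)
    return PromoterAssignment(gene.symbol, window, BASIS_GENE_TSS, OWNER_GENE)


def assign_mirna_promoters(
    mirnas: Sequence[MiRNARecord],
    genes: Sequence[GeneRecord],
    cfg: Config,
) -> list[PromoterAssignment]:
    """One promoter assignment per precursor.

    Precedence: genic precursors (intronic / 3'UTR-hosted) take the host
    gene's promoter; clustered precursors share a promoter upstream of the
    cluster span (the cluster rule wins over the host rule when
    ``cluster_promoter_wins`` is set); remaining precursors get a window
    upstream of the hairpin itself.  Antisense hosts do not share a
    transcription unit with the precursor and are treated as intergenic
    when ``antisense_host_as_intergenic`` is set.
    """
    gene_index = {g.symbol: g for g in genes}
    clusters = cluster_mirnas(mirnas, cfg)
    in_cluster: dict[str, MiRNACluster] = {}
    for cl in clusters:
        if len(cl.members) > 1:
            for pid in cl.members:
                in_cluster[pid] = cl

    out = []
    for rec in sorted(mirnas, key=lambda r: r.precursor_id):
        genic = rec.is_genic or (
            rec.host_relation == "antisense"
            and not cfg.antisense_host_as_intergenic
        )
        cl = in_cluster.get(rec.precursor_id)
        if cl is not None and (cfg.cluster_promoter_wins or not genic):
            window = _upstream_window(cl.interval, cfg.mirna_promoter_len)
            basis = BASIS_CLUSTER
        elif genic:
            host = gene_index.get(rec.host_gene)
            if host is None:
                raise UnresolvedHostError(
                    f"host gene {rec.host_gene!r} of {rec.precursor_id} "
                    "not found in the gene annotation"
                )
            window = _upstream_window(host.interval, cfg.mirna_promoter_len)
            basis = BASIS_HOST_GENE
        else:
            window = _upstream_window(rec.interval, cfg.mirna_promoter_len)
            basis = BASIS_PRECURSOR
        out.append(
            PromoterAssignment(rec.precursor_id, window, basis, OWNER_MIRNA)
        )
    return out


def map_tfbs_to_promoters(
    hits: Sequence[TFBSHit],
    promoters: Sequence[PromoterAssignment],
    cfg: Config,
) -> list[MappedHit]:
    """Filter hits and attach them to overlapping promoters.

    A hit is kept when its Z score is strictly above ``z_cutoff``, it is
    conserved (when ``require_tfbs_conserved``), and it overlaps a promoter
    window by >= 1 bp.  A hit spanning several promoters yields one record
    per owner.
    """
    trees: dict[str, IntervalTree] = {}
    for i, pa in enumerate(promoters):
        trees.setdefault(pa.interval.chrom, IntervalTree()).addi(
            pa.interval.start, pa.interval.end, i
        )
    out = []
    for hit in hits:
        if hit.z_score <= cfg.z_cutoff:
            continue
        if cfg.require_tfbs_conserved and not hit.conserved:
            continue
        tree = trees.get(hit.interval.chrom)
        if tree is None:
            continue
        owners = sorted(
            (promoters[iv.data] for iv in tree.overlap(
                hit.interval.start, hit.interval.end)),
            key=lambda pa: (pa.owner_kind, pa.owner),
        )
        for pa in owners:
            out.append(MappedHit(hit, pa.owner, pa.owner_kind))
    return out


def map_tfbs_bruteforce(
    hits: Sequence[TFBSHit],
    promoters: Sequence[PromoterAssignment],
    cfg: Config,
) -> list[MappedHit]:
    """All-pairs scanning reference for :func:`map_tfbs_to_promoters`."""
    out = []
    for hit in hits:
        if hit.z_score <= cfg.z_cutoff:
            continue
        if cfg.require_tfbs_conserved and not hit.conserved:
            continue
        for pa in sorted(promoters, key=lambda p: (p.owner_kind, p.owner)):
            if hit.interval.overlaps(pa.interval):
                out.append(MappedHit(hit, pa.owner, pa.owner_kind))
    return out
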