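"""Categorise SNPs by overlap with regulatory elements.

Categories: miRNA target sites (3'UTR seed matches), TFBS hits mapped to
gene promoters, TFBS hits mapped to miRNA promoters, pre-miRNA hairpin
bodies, and their flanking windows (``snp_flank`` bp each side, boundary
inclusive).  One SNP may fall into several categories; within one
precursor, body and flank are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .network import OWNER_GENE, OWNER_MIRNA, MappedHit
from .types import Config, MiRNARecord, SNPRecord, TargetPair

CAT_TARGET_SITE = "target_site"
CAT_TFBS_GENE = "tfbs_gene_promoter"
CAT_TFBS_MIRNA = "tfbs_mirna_promoter"
CAT_PRE_MIRNA = "pre_mirna"
CAT_PRE_MIRNA_FLANK = "pre_mirna_flank"

ALL_CATEGORIES = (
    CAT_TARGET_SITE,
    CAT_TFBS_GENE,
    CAT_TFBS_MIRNA,
    CAT_PRE_MIRNA,
    CAT_PRE_MIRNA_FLANK,
)


@dataclass
class SNPAnnotation:
    rsid: str
    categories: set[str] = field(default_factory=set)
    #: category -> sorted ids of the overlapped features
    elements: dict[str, list[str]] = field(default_factory=dict)
    #: precursor id -> distance in bp, for flank hits
    flank_distance: dict[str, int] = field(default_factory=dict)

    def _add(self, category: str, element: str) -> None:
        self.categories.add(category)
        bucket = self.elements.setdefault(category, [])
        if element not in bucket:
            bucket.append(element)
            bucket.sort()


def annotate_snps(
    snps: Sequence[SNPRecord],
    target_sites: Sequence[TargetPair],
    mapped_hits: Sequence[MappedHit],
    mirnas: Sequence[MiRNARecord],
    cfg: Config,
) -> list[SNPAnnotation]:
    """Single-base overlap tests of each SNP against every feature class.

    Target pairs without site coordinates are skipped (nothing to overlap).
    A SNP inside a pre-miRNA body is not additionally counted in that
    precursor's flank.
    """
    out = []
    for snp in sorted(snps, key=lambda s: (s.chrom, s.position, s.rsid)):
        ann = SNPAnnotation(snp.rsid)
        for pair in target_sites:
            if pair.site is not None and pair.site.contains_point(
                snp.chrom, snp.position
            ):
                ann._add(CAT_TARGET_SITE, f"{pair.mirna}->{pair.gene}")
        for mh in mapped_hits:
            if mh.hit.interval.contains_point(snp.chrom, snp.position):
                cat = CAT_TFBS_GENE if mh.owner_kind == OWNER_GENE else CAT_TFBS_MIRNA
                ann._add(cat, f"{mh.hit.matrix_id}@{mh.owner}")
        for rec in mirnas:
            iv = rec.interval
            if iv.contains_point(snp.chrom, snp.position):
                ann._add(CAT_PRE_MIRNA, rec.precursor_id)
            elif iv.chrom == snp.chrom:
                dist = iv.distance_to_point(snp.position)
                if dist <= cfg.snp_flank:
                    ann._add(CAT_PRE_MIRNA_FLANK, rec.precursor_id)
                    ann.flank_distance[rec.precursor_id] = dist
        out.append(ann)
    return out


def summarize_snp_annotations(
    annotations: Sequence[SNPAnnotation],
) -> dict[str, dict[str, int]]:
    """Per category: number of SNPs and number of distinct owner features.

    For TFBS categories the owner feature is the promoter owner (gene or
    precursor), matching summaries like "N SNPs on TFBSs of M genes".
    """
    summary = {c: {"n_snps": 0, "n_features": 0} for c in ALL_CATEGORIES}
    owners: dict[str, set[str]] = {c: set() for c in ALL_CATEGORIES}
    for ann in annotations:
        for cat in ann.categories:
            summary[cat]["n_snps"] += 1
            for element in ann.elements.get(cat, []):
                owner = element.split("@", 1)[1] if "@" in element else element
                owners[cat].add(owner)
    for cat in ALL_CATEGORIES:
        summary[cat]["n_features"] = len(owners[cat])
    return summary
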