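"""Core domain types for miRNA-TF regulatory network analysis.

All genomic coordinates are stored in a single internal convention:
0-based, half-open ``[start, end)``, as in BED.  Dialects that use 1-based
inclusive coordinates (GFF3, display strings like ``17: 6861658-6861744``)
are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import yaml

INTERGENIC = "INTERGENIC"

#: conservation classes: V vertebrate, M mammal-specific, P primate-specific,
#: A conserved down to Drosophila
CONSERVATION_CLASSES = frozenset({"V", "M", "P", "A"})

HOST_RELATIONS = frozenset({"intronic", "utr3", "antisense", "intergenic"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """Distance in bp from a point to the span (0 when inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    @classmethod
    def from_one_based(
        cls, chrom: str, start: int, end: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (GFF3 / display style)."""
        return cls(chrom, start - 1, end, strand)

    def to_one_based(self) -> tuple[str, int, int, str]:
        """Emit (chrom, start, end, strand) in 1-based inclusive coordinates."""
        return (self.chrom, self.start + 1, self.end, self.strand)

    def five_prime(self) -> int:
        """The 5' boundary position (internal convention)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class MiRNARecord:
    """A miRNA precursor (pre-miRNA hairpin locus).

    Precursors with identical mature products share a ``family_id``
    (e.g. hsa-miR-9-1/-2/-3 all belong to family hsa-miR-9).
    """

    precursor_id: str
    family_id: str
    mature_ids: tuple[str, ...]
    interval: GenomicInterval
    host_gene: str = INTERGENIC
    host_relation: str = "intergenic"
    conservation_class: str = "V"

    def __post_init__(self) -> None:
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(
                f"unknown conservation class {self.conservation_class!r} "
                f"for {self.precursor_id}"
            )
        if self.host_relation not in HOST_RELATIONS:
            raise ValueError(
                f"unknown host relation {self.host_relation!r} "
                f"for {self.precursor_id}"
            )
        if self.host_relation == "intergenic" and self.host_gene != INTERGENIC:
            raise ValueError(
                f"intergenic precursor {self.precursor_id} must have "
                f"host_gene={INTERGENIC}"
            )

    @property
    def is_genic(self) -> bool:
        """True when the precursor shares a transcription unit with its host.

        Antisense-hosted precursors overlap a gene but on the opposite
        strand, so they do not share its promoter and are not genic here.
        """
        return self.host_relation in ("intronic", "utr3")


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with its body span and transcription start site."""

    symbol: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        return self.interval.five_prime()


@dataclass(frozen=True)
class TFBSHit:
    """One predicted transcription-factor binding-site placement.

    ``matrix_id`` is a position-weight-matrix identifier (e.g. V$NGFIC_01);
    a matrix may map to several TF gene symbols. ``conserved`` flags
    human/mouse/rat conservation of the placement.
    """

    matrix_id: str
    consensus: str
    tf_symbols: tuple[str, ...]
    interval: GenomicInterval
    z_score: float
    conserved: bool = True

    def __post_init__(self) -> None:
        if not self.tf_symbols:
            raise ValueError(f"{self.matrix_id}: tf_symbols must be non-empty")
        if not (self.z_score == self.z_score and abs(self.z_score) != float("inf")):
            raise ValueError(f"{self.matrix_id}: z_score must be finite")


@dataclass(frozen=True)
class TargetPair:
    """A predicted miRNA -> gene targeting relation (3'UTR seed match)."""

    mirna: str
    gene: str
    site: Optional[GenomicInterval] = None
    site_conserved: bool = True

    def key(self) -> tuple:
        return (self.mirna, self.gene, self.site)


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide polymorphism; position is internal 0-based."""

    rsid: str
    chrom: str
    position: int
    alleles: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"{self.rsid}: position must be >= 0")


@dataclass
class Config:
    """All numeric thresholds of the pipeline, with the defaults used
    throughout the analysis.

    Promoters are fixed-length windows immediately 5' of a TSS, precursor,
    cluster or host gene; TFBS hits must clear ``z_cutoff`` (strict >) and,
    by default, be conserved; miRNA target sites must be conserved except
    for primate-specific (class P) miRNAs.
    """

    gene_promoter_len: int = 5000
    mirna_promoter_len: int = 5000
    cluster_max_gap: int = 5000
    cluster_same_strand: bool = True
    z_cutoff: float = 2.33
    require_tfbs_conserved: bool = True
    require_site_conserved: bool = True
    antisense_host_as_intergenic: bool = True
    cluster_promoter_wins: bool = True
    core_min_tfs: int = 3
    core_min_mirnas: int = 3
    core_min_targets: int = 3
    count_self_edges: bool = False
    group_level_counting: bool = True
    snp_flank: int = 100
    permutation_reps: int = 10000
    conservative_permutation_p: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gene_promoter_len",
            "mirna_promoter_len",
            "cluster_max_gap",
            "snp_flank",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.permutation_reps < 1:
            raise ValueError("permutation_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def family_of(precursor_id: str) -> str:
    """Derive the family name from a precursor name.

    hsa-miR-9-1 -> hsa-miR-9; hsa-miR-181b-2 -> hsa-miR-181b;
    hsa-let-7g and hsa-miR-195 are unchanged.  A trailing all-digit token
    is a duplicate-locus index only when the token before it already
    carries the family number (contains a digit), so miR-195 keeps its
    name while miR-92a-2 maps to miR-92a.
    """
    parts = precursor_id.split("-")
    if (
        len(parts) >= 3
        and parts[-1].isdigit()
        and any(ch.isdigit() for ch in parts[-2])
    ):
        return "-".join(parts[:-1])
    return precursor_id


def mature_to_precursors(mirnas: Iterable[MiRNARecord]) -> dict[str, list[str]]:
    """Expansion table mapping mature/family names to precursor ids.

    Target predictions are stated at the mature/family level while loops
    are enumerated per precursor, so one mature name may expand to several
    precursors (e.g. hsa-miR-9 -> hsa-miR-9-1/-2/-3).
    """
    table: dict[str, list[str]] = {}
    for rec in mirnas:
        names = set(rec.mature_ids) | {rec.family_id, rec.precursor_id}
        for name in names:
            table.setdefault(name, [])
            if rec.precursor_id not in table[name]:
                table[name].append(rec.precursor_id)
    for name in table:
        table[name].sort()
    return table
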