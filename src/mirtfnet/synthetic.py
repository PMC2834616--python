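"""Synthetic input bundles with planted, fully known regulatory structure.

The generator lays out miniature annotation files in the same dialects the
pipeline ingests (genes BED, miRNA GFF3, TFBS track, target-pair TSV, SNP
TSV) and plants a configurable number of feed-forward loops, miRNA-TF
feedback loops and categorised SNPs.  Every planted element is written to
a truth table, so pipeline output can be compared against ground truth
without consulting generator internals.

Planted TFBS hits always clear the retention criteria (Z above the cutoff,
conserved, inside the right promoter window); decoy hits each fail at
least one criterion (sub-threshold Z, non-conserved, or placed on a
feature-free chromosome), and promoters of planted features never overlap,
so planted loops can neither merge nor be created by accidental adjacency.
Only coordinates, labels and scores are simulated - no sequence content.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as mio
from .fixtures import FFLRow, load_paper_fixtures
from .network import (
    EDGE_MIRNA_GENE,
    OWNER_GENE,
    OWNER_MIRNA,
    Edge,
    MappedHit,
)
from .promoters import assign_gene_promoter, assign_mirna_promoters
from .types import (
    INTERGENIC,
    Config,
    GenomicInterval,
    GeneRecord,
    MiRNARecord,
    SNPRecord,
    TargetPair,
    TFBSHit,
    family_of,
)

_CHROMS = ("chrS1", "chrS2", "chrS3")
_DECOY_CHROM = "chrD"


@dataclass
class SimConfig:
    """Knobs of the synthetic generator.

    Defaults describe a small but structured study: a few dozen candidate
    genes, a dozen precursors of which roughly a third sit in host genes
    and a quarter in 2-member clusters, a 7-loop planted FFL backbone with
    a handful of mutual feedback loops, and around two decoy binding sites
    per promoter drawn from a sub-threshold Z distribution.
    """

    n_genes: int = 40
    n_mirnas: int = 12
    frac_genic: float = 0.3
    frac_clustered: float = 0.25
    n_matrices: int = 24
    planted_ffls: int = 7
    planted_feedback: int = 4
    decoy_tfbs_rate: float = 2.0
    z_decoy_mean: float = 1.5
    z_decoy_sd: float = 0.5
    z_planted_min: float = 2.5
    z_planted_max: float = 4.0
    nonconserved_fraction: float = 0.3
    n_decoy_pairs: int = 30
    n_snps_per_category: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_genic", "frac_clustered", "nonconserved_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        n_genic = round(self.frac_genic * self.n_mirnas)
        if self.planted_ffls + self.planted_feedback > self.n_matrices:
            raise ValueError("not enough matrices for the planted loops")
        if self.planted_ffls + self.planted_feedback + n_genic + 1 > self.n_genes:
            raise ValueError(
                "not enough genes for planted targets, TF genes and hosts"
            )
        if (self.planted_ffls or self.planted_feedback) and self.n_mirnas < 1:
            raise ValueError("planted loops require at least one miRNA")
        if self.n_snps_per_category > 0 and self.planted_ffls < 1:
            raise ValueError("planted SNPs require at least one planted FFL")


@dataclass
class GeneratedBundle:
    """File paths plus the planted truth, as written to disk."""

    out_dir: Path
    paths: dict[str, Path]
    genes: list[GeneRecord]
    mirnas: list[MiRNARecord]
    tfbs_hits: list[TFBSHit]
    target_pairs: list[TargetPair]
    snps: list[SNPRecord]
    truth_ffls: list[tuple[str, str, str]]  # (matrix_id, mirna, gene)
    truth_feedback: list[tuple[str, str, str]]  # (matrix_id, mirna, tf_gene)
    truth_snps: list[tuple[str, str, str]]  # (rsid, category, element)
    collisions: dict[str, int]


def _gene_layout(i: int, n: int) -> GeneRecord:
    chrom = _CHROMS[i % len(_CHROMS)]
    block = i // len(_CHROMS)
    start = 1_000_000 + block * 100_000
    strand = "+" if i % 2 == 0 else "-"
    return GeneRecord(f"G{i:03d}", GenomicInterval(chrom, start, start + 20_000, strand))


def generate_bundle(sim: SimConfig, out_dir) -> GeneratedBundle:
    """Write the five input files plus truth tables under ``out_dir``.

    Deterministic: the same ``sim`` (including ``rng_seed``) produces
    byte-identical output files.
    """
    rng = np.random.default_rng(sim.rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = Config()

    # -- gene roles ---------------------------------------------------
    n_genic = round(sim.frac_genic * sim.n_mirnas)
    pf, pb = sim.planted_ffls, sim.planted_feedback
    genes = [_gene_layout(i, sim.n_genes) for i in range(sim.n_genes)]
    ffl_genes = genes[:pf]
    tf_genes = [
        dataclasses.replace(genes[pf + j], symbol=f"TFG{j:02d}")
        for j in range(pb)
    ]
    for j in range(pb):
        genes[pf + j] = tf_genes[j]
    host_genes = genes[pf + pb : pf + pb + n_genic]
    decoy_genes = genes[pf + pb + n_genic :]

    # -- miRNA layout -------------------------------------------------
    n_clustered = 2 * int(round(sim.frac_clustered * sim.n_mirnas / 2))
    mirnas: list[MiRNARecord] = []
    for i in range(sim.n_mirnas):
        pid = f"syn-miR-{i:02d}"
        if i < n_clustered:
            # consecutive pairs 2 kb apart on one strand
            pair, within = divmod(i, 2)
            chrom = _CHROMS[pair % len(_CHROMS)]
            base = 10_000_000 + (pair // len(_CHROMS)) * 100_000
            start = base + within * 2_100
            iv = GenomicInterval(chrom, start, start + 100, "+")
            host, rel = INTERGENIC, "intergenic"
        elif i < n_clustered + n_genic:
            host_gene = host_genes[i - n_clustered]
            giv = host_gene.interval
            start = giv.start + 5_000
            iv = GenomicInterval(giv.chrom, start, start + 100, giv.strand)
            host, rel = host_gene.symbol, "intronic"
        else:
            k = i - n_clustered - n_genic
            chrom = _CHROMS[k % len(_CHROMS)]
            base = 20_000_000 + (k // len(_CHROMS)) * 100_000
            iv = GenomicInterval(chrom, base, base + 100, "+" if k % 2 else "-")
            host, rel = INTERGENIC, "intergenic"
        mirnas.append(
            MiRNARecord(pid, family_of(pid), (pid,), iv, host, rel, "V")
        )

    gene_promoters = {g.symbol: assign_gene_promoter(g, cfg) for g in genes}
    mirna_promoters = {
        pa.owner: pa for pa in assign_mirna_promoters(mirnas, genes, cfg)
    }

    # -- matrix catalog ----------------------------------------------
    catalog: dict[str, tuple[str, tuple[str, ...]]] = {}
    for k in range(sim.n_matrices):
        mid = f"V$SYN{k:02d}"
        if k < pf:
            symbols: tuple[str, ...] = (f"TFA{k:02d}",)
        elif k < pf + pb:
            symbols = (tf_genes[k - pf].symbol,)
        else:
            symbols = (f"TFD{k:02d}",)
        catalog[mid] = (f"CONSENSUS{k:02d}", symbols)

    hits: list[TFBSHit] = []
    slot_counter: dict[str, int] = {}

    def _place(window: GenomicInterval, matrix_id: str, z: float,
               conserved: bool) -> TFBSHit:
        slot = slot_counter.get(f"{window.chrom}:{window.start}", 0)
        slot_counter[f"{window.chrom}:{window.start}"] = slot + 1
        start = window.start + (slot * 50) % max(window.length - 15, 1)
        consensus, symbols = catalog[matrix_id]
        hit = TFBSHit(
            matrix_id, consensus, symbols,
            GenomicInterval(window.chrom, start, start + 15, window.strand),
            round(float(z), 3), conserved,
        )
        hits.append(hit)
        return hit

    # -- planted FFLs -------------------------------------------------
    truth_ffls: list[tuple[str, str, str]] = []
    pairs: list[TargetPair] = []
    ffl_gene_hits: list[TFBSHit] = []
    ffl_mirna_hits: list[TFBSHit] = []
    for i in range(pf):
        matrix = f"V$SYN{i:02d}"
        gene = ffl_genes[i]
        mirna = mirnas[i % sim.n_mirnas]
        z1 = rng.uniform(sim.z_planted_min, sim.z_planted_max)
        z2 = rng.uniform(sim.z_planted_min, sim.z_planted_max)
        gh = _place(gene_promoters[gene.symbol].interval, matrix, z1, True)
        ffl_gene_hits.append(gh)
        mh = _place(mirna_promoters[mirna.precursor_id].interval, matrix, z2, True)
        ffl_mirna_hits.append(mh)
        giv = gene.interval
        site = GenomicInterval(
            giv.chrom, giv.end - 300 + i * 10, giv.end - 293 + i * 10, giv.strand
        )
        pairs.append(TargetPair(mirna.precursor_id, gene.symbol, site, True))
        truth_ffls.append((matrix, mirna.precursor_id, gene.symbol))

    # -- planted feedback loops ---------------------------------------
    truth_feedback: list[tuple[str, str, str]] = []
    for j in range(pb):
        matrix = f"V$SYN{pf + j:02d}"
        tf_gene = tf_genes[j]
        mirna = mirnas[(pf + j) % sim.n_mirnas]
        z = rng.uniform(sim.z_planted_min, sim.z_planted_max)
        _place(mirna_promoters[mirna.precursor_id].interval, matrix, z, True)
        giv = tf_gene.interval
        site = GenomicInterval(
            giv.chrom, giv.end - 300 + j * 10, giv.end - 293 + j * 10, giv.strand
        )
        pairs.append(TargetPair(mirna.precursor_id, tf_gene.symbol, site, True))
        truth_feedback.append((matrix, mirna.precursor_id, tf_gene.symbol))

    # -- decoy TFBS hits ----------------------------------------------
    all_windows = [pa.interval for pa in gene_promoters.values()] + [
        pa.interval for pa in mirna_promoters.values()
    ]
    decoy_matrix_pool = [f"V$SYN{k:02d}" for k in range(pf + pb, sim.n_matrices)]
    if not decoy_matrix_pool:
        decoy_matrix_pool = ["V$SYN00"]
    n_decoys = int(round(sim.decoy_tfbs_rate * (sim.n_genes + sim.n_mirnas)))
    collisions = {"subthreshold_z_above_cutoff": 0}
    for d in range(n_decoys):
        matrix = decoy_matrix_pool[d % len(decoy_matrix_pool)]
        z = float(rng.normal(sim.z_decoy_mean, sim.z_decoy_sd))
        mode = d % 3
        if mode == 0:  # in a promoter but non-conserved
            window = all_windows[int(rng.integers(len(all_windows)))]
            _place(window, matrix, z, False)
        elif mode == 1:  # conserved and possibly strong, but no promoter
            start = 1_000_000 + d * 10_000
            consensus, symbols = catalog[matrix]
            hits.append(
                TFBSHit(matrix, consensus, symbols,
                        GenomicInterval(_DECOY_CHROM, start, start + 15, "+"),
                        round(z, 3), True)
            )
        else:  # in a promoter, conserved, but sub-threshold Z
            window = all_windows[int(rng.integers(len(all_windows)))]
            conserved = True
            if z > cfg.z_cutoff:
                # drawn tail value would pass the filter; demote and report
                collisions["subthreshold_z_above_cutoff"] += 1
                conserved = False
            _place(window, matrix, z, conserved)

    # -- decoy target pairs -------------------------------------------
    for d in range(sim.n_decoy_pairs):
        gene = decoy_genes[int(rng.integers(len(decoy_genes)))]
        mirna = mirnas[int(rng.integers(sim.n_mirnas))]
        conserved = bool(rng.random() >= sim.nonconserved_fraction)
        giv = gene.interval
        off = int(rng.integers(0, 200)) * 10
        site = GenomicInterval(
            giv.chrom, giv.start + 2_000 + off, giv.start + 2_007 + off, giv.strand
        )
        pair = TargetPair(mirna.precursor_id, gene.symbol, site, conserved)
        if pair.key() not in {p.key() for p in pairs}:
            pairs.append(pair)

    # -- planted SNPs --------------------------------------------------
    truth_snps: list[tuple[str, str, str]] = []
    snps: list[SNPRecord] = []
    rs = 1000

    def _snp(chrom: str, pos: int, category: str, element: str) -> None:
        nonlocal rs
        snps.append(SNPRecord(f"rs{rs}", chrom, pos, "A/G"))
        truth_snps.append((f"rs{rs}", category, element))
        rs += 1

    intergenic_mirnas = [
        m for m in mirnas
        if m.host_relation == "intergenic"
        and m.precursor_id not in {t[1] for t in truth_ffls + truth_feedback}
    ] or [m for m in mirnas if m.host_relation == "intergenic"]
    for s in range(sim.n_snps_per_category):
        ffl_i = s % pf
        pair = pairs[ffl_i]
        _snp(pair.site.chrom, pair.site.start + 2, "target_site",
             f"{pair.mirna}->{pair.gene}")
        gh = ffl_gene_hits[ffl_i]
        _snp(gh.interval.chrom, gh.interval.start + 3, "tfbs_gene_promoter",
             f"{gh.matrix_id}@{truth_ffls[ffl_i][2]}")
        mh = ffl_mirna_hits[ffl_i]
        _snp(mh.interval.chrom, mh.interval.start + 3, "tfbs_mirna_promoter",
             f"{mh.matrix_id}@{truth_ffls[ffl_i][1]}")
        body = intergenic_mirnas[s % len(intergenic_mirnas)]
        _snp(body.interval.chrom, body.interval.start + 10, "pre_mirna",
             body.precursor_id)
        flank_m = intergenic_mirnas[(s + 1) % len(intergenic_mirnas)]
        dist = 20 + 30 * s
        _snp(flank_m.interval.chrom, flank_m.interval.end - 1 + dist,
             "pre_mirna_flank", flank_m.precursor_id)
    # background SNPs hitting nothing
    for s in range(sim.n_snps_per_category):
        snps.append(SNPRecord(f"rs{rs}", _DECOY_CHROM, 500 + s * 97, "C/T"))
        rs += 1

    # -- write files ----------------------------------------------------
    paths = {
        "genes": out_dir / "genes.bed",
        "mirnas": out_dir / "mirnas.gff3",
        "tfbs": out_dir / "tfbs_track.tsv",
        "matrix_map": out_dir / "matrix_tf_map.tsv",
        "pairs": out_dir / "target_pairs.tsv",
        "snps": out_dir / "snps.tsv",
        "focal_genes": out_dir / "focal_genes.txt",
        "truth_ffls": out_dir / "truth_ffls.tsv",
        "truth_feedback": out_dir / "truth_feedback.tsv",
        "truth_snps": out_dir / "truth_snps.tsv",
        "manifest": out_dir / "manifest.json",
        "sim_config": out_dir / "sim_config.yaml",
    }
    mio.write_gene_bed(genes, paths["genes"])
    mio.write_mirna_annotation(mirnas, paths["mirnas"])
    hits_sorted = sorted(
        hits, key=lambda h: (h.interval.chrom, h.interval.start, h.matrix_id)
    )
    mio.write_tfbs_track(hits_sorted, paths["tfbs"])
    mio.write_matrix_tf_map(
        {m: syms for m, (_c, syms) in catalog.items()}, paths["matrix_map"]
    )
    mio.write_target_pairs(pairs, paths["pairs"])
    mio.write_snp_table(snps, paths["snps"])
    # focal gene list: the genes carrying planted regulation, mirroring a
    # disease candidate-gene list against the full gene universe
    with open(paths["focal_genes"], "w") as fh:
        for sym in sorted({g.symbol for g in ffl_genes} | {g.symbol for g in tf_genes}):
            fh.write(sym + "\n")
    _write_truth(paths["truth_ffls"], ("matrix_id", "mirna", "gene"), truth_ffls)
    _write_truth(
        paths["truth_feedback"], ("matrix_id", "mirna", "tf_gene"), truth_feedback
    )
    _write_truth(paths["truth_snps"], ("rsid", "category", "element"), truth_snps)
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "n_genes": sim.n_genes,
                "n_mirnas": sim.n_mirnas,
                "planted_ffls": pf,
                "planted_feedback": pb,
                "n_decoy_hits": n_decoys,
                "collisions": collisions,
                "rng_seed": sim.rng_seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    with open(paths["sim_config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(sim), fh, sort_keys=True)

    return GeneratedBundle(
        out_dir=out_dir, paths=paths, genes=genes, mirnas=mirnas,
        tfbs_hits=hits_sorted, target_pairs=pairs, snps=snps,
        truth_ffls=sorted(truth_ffls), truth_feedback=sorted(truth_feedback),
        truth_snps=sorted(truth_snps), collisions=collisions,
    )


def _write_truth(path: Path, header: tuple[str, ...], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in sorted(rows):
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Edge bundle reconstructed from the reference FFL table
# ---------------------------------------------------------------------------


@dataclass
class Table2Bundle:
    """Matrix-level, pre-merge inputs implied by the reference FFL table."""

    mapped_hits: list[MappedHit]
    mirna_gene_edges: list[Edge]


def table2_edge_bundle(rows: Optional[Sequence[FFLRow]] = None) -> Table2Bundle:
    """Expand the bundled FFL table into matrix-level edge sets.

    The source table does not print TFBS coordinates, so placements are
    synthesised: matrices listed together in one row (already merged by
    redundancy) are placed overlapping within the owner promoter; matrices
    from different rows occupy disjoint slots.  Feeding the result through
    group merging and FFL enumeration reproduces the table.
    """
    if rows is None:
        rows = load_paper_fixtures().ffl_table
    mapped: list[MappedHit] = []
    slot: dict[str, int] = {}
    for row in rows:
        for owner, kind in ((row.gene, OWNER_GENE), (row.mirna, OWNER_MIRNA)):
            s = slot.get(owner, 0)
            slot[owner] = s + 1
            start = 1_000 * (s + 1)
            for matrix_id in row.matrix_ids:
                hit = TFBSHit(
                    matrix_id=matrix_id,
                    consensus=row.consensus,
                    tf_symbols=row.tf_symbols,
                    interval=GenomicInterval("chrF", start, start + 20, "+"),
                    z_score=2.5,
                    conserved=True,
                )
                mapped.append(MappedHit(hit, owner, kind))
    edge_acc: dict[tuple[str, str], set[str]] = {}
    for row in rows:
        edge_acc.setdefault((row.mirna, row.gene), set()).add(
            f"{row.mirna}->{row.gene}"
        )
    edges = [
        Edge(m, g, EDGE_MIRNA_GENE, frozenset(ev))
        for (m, g), ev in sorted(edge_acc.items())
    ]
    return Table2Bundle(mapped, edges)
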