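"""Readers and writers for the five input dialects and network exports.

Dialects and their on-disk coordinate conventions:

====================  =======================  ======================
input                 format                   coordinates
====================  =======================  ======================
gene annotation       BED6                     0-based half-open
miRNA precursors      GFF3 with attributes     1-based inclusive
TFBS track            BED-like + sidecar map   0-based half-open
target pairs          TSV                      0-based half-open
SNP table             TSV                      1-based single base
====================  =======================  ======================

Every reader is total on the dialect its paired writer emits: a write
followed by a read reproduces the original value list exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx

from .network import (
    EDGE_MIRNA_GENE,
    EDGE_MIRNA_TF,
    EDGE_TF_GENE,
    EDGE_TF_MIRNA,
    NODE_GENE,
    NODE_MIRNA,
    NODE_TF,
    RegulatoryNetwork,
)
from .types import (
    CONSERVATION_CLASSES,
    GenomicInterval,
    GeneRecord,
    MiRNARecord,
    SNPRecord,
    TargetPair,
    TFBSHit,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed input line; carries file path and 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _attr_dict(path: PathLike, lineno: int, field: str) -> dict[str, str]:
    out = {}
    for item in field.rstrip(";").split(";"):
        if "=" not in item:
            raise ParseError(path, lineno, f"malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# miRNA precursor annotation (GFF3 dialect, 1-based inclusive)
# ---------------------------------------------------------------------------


def read_mirna_annotation(path: PathLike) -> list[MiRNARecord]:
    records = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(path, lineno, f"expected 9 GFF3 columns, got {len(cols)}")
        chrom, _src, _type, start_s, end_s, _score, strand, _phase, attrs_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(
                path, lineno, f"malformed coordinates {start_s!r}-{end_s!r}"
            ) from None
        attrs = _attr_dict(path, lineno, attrs_s)
        for req in ("ID", "host_gene", "host_relation", "conservation"):
            if req not in attrs:
                raise ParseError(path, lineno, f"missing attribute {req!r}")
        cons = attrs["conservation"]
        if cons not in CONSERVATION_CLASSES:
            raise ParseError(path, lineno, f"unknown conservation code {cons!r}")
        try:
            interval = GenomicInterval.from_one_based(chrom, start, end, strand)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        records.append(
            MiRNARecord(
                precursor_id=attrs["ID"],
                family_id=attrs.get("family", attrs["ID"]),
                mature_ids=tuple(
                    m for m in attrs.get("matures", "").split(",") if m
                ),
                interval=interval,
                host_gene=attrs["host_gene"],
                host_relation=attrs["host_relation"],
                conservation_class=cons,
            )
        )
    return records


def write_mirna_annotation(records: Sequence[MiRNARecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            chrom, start, end, strand = r.interval.to_one_based()
            attrs = (
                f"ID={r.precursor_id};family={r.family_id};"
                f"matures={','.join(r.mature_ids)};host_gene={r.host_gene};"
                f"host_relation={r.host_relation};conservation={r.conservation_class}"
            )
            fh.write(
                f"{chrom}\tmirtfnet\tmiRNA_primary_transcript\t{start}\t{end}"
                f"\t.\t{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation (BED6, 0-based half-open)
# ---------------------------------------------------------------------------


def read_gene_bed(path: PathLike) -> list[GeneRecord]:
    genes = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 6:
            raise ParseError(path, lineno, "expected BED6 (6 columns)")
        chrom, start_s, end_s, name, _score, strand = cols[:6]
        try:
            interval = GenomicInterval(chrom, int(start_s), int(end_s), strand)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        genes.append(GeneRecord(name, interval))
    return genes


def write_gene_bed(genes: Sequence[GeneRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.symbol}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# TFBS track (BED-like, 0-based half-open) + matrix -> TF sidecar
# ---------------------------------------------------------------------------

_TFBS_HEADER = [
    "chrom", "start", "end", "matrix_id", "z_score", "strand",
    "consensus", "conserved",
]


def read_matrix_tf_map(path: PathLike) -> dict[str, tuple[str, ...]]:
    """Two-column sidecar: matrix_id <tab> comma-separated TF symbols."""
    out: dict[str, tuple[str, ...]] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(path, lineno, "expected 2 columns (matrix, symbols)")
        if cols[0] == "matrix_id":
            continue
        out[cols[0]] = tuple(s.strip() for s in cols[1].split(",") if s.strip())
    return out


def write_matrix_tf_map(
    table: dict[str, tuple[str, ...]], path: PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("matrix_id\ttf_symbols\n")
        for matrix_id in sorted(table):
            fh.write(f"{matrix_id}\t{','.join(table[matrix_id])}\n")


def read_tfbs_track(
    path: PathLike,
    tf_map: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[TFBSHit]:
    """Read a conserved-TFBS track.

    TF symbols come from column 9 when present, else from the sidecar
    ``tf_map``.  No filtering is applied here; Z and conservation cutoffs
    belong to the promoter-mapping stage.
    """
    hits = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[: len(_TFBS_HEADER)] == _TFBS_HEADER or cols[0] == "chrom":
            continue
        if len(cols) < 8:
            raise ParseError(
                path, lineno,
                "expected >= 8 columns (chrom start end matrix z strand "
                "consensus conserved [symbols])",
            )
        chrom, start_s, end_s, matrix_id, z_s, strand, consensus, cons_s = cols[:8]
        try:
            z = float(z_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric Z score {z_s!r}") from None
        if len(cols) >= 9 and cols[8]:
            symbols = tuple(s.strip() for s in cols[8].split(",") if s.strip())
        elif tf_map is not None and matrix_id in tf_map:
            symbols = tf_map[matrix_id]
        else:
            raise ParseError(
                path, lineno,
                f"no TF symbols for {matrix_id!r} (none inline, none in sidecar)",
            )
        try:
            interval = GenomicInterval(chrom, int(start_s), int(end_s), strand)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        hits.append(
            TFBSHit(
                matrix_id=matrix_id,
                consensus=consensus,
                tf_symbols=symbols,
                interval=interval,
                z_score=z,
                conserved=cons_s not in ("0", "false", "False"),
            )
        )
    return hits


def write_tfbs_track(hits: Sequence[TFBSHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TFBS_HEADER + ["tf_symbols"]) + "\n")
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.matrix_id}\t"
                f"{h.z_score!r}\t{iv.strand}\t{h.consensus}\t"
                f"{1 if h.conserved else 0}\t{','.join(h.tf_symbols)}\n"
            )


# ---------------------------------------------------------------------------
# miRNA target pairs (TSV)
# ---------------------------------------------------------------------------

_PAIR_HEADER = [
    "mirna", "gene", "site_chrom", "site_start", "site_end", "site_strand",
    "site_conserved",
]


def read_target_pairs(path: PathLike) -> list[TargetPair]:
    """Read predicted miRNA -> gene pairs; duplicates are dropped with a
    warning stating how many were removed."""
    pairs: list[TargetPair] = []
    seen: set = set()
    dupes = 0
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "mirna":
            continue
        if len(cols) < 7:
            raise ParseError(path, lineno, "expected 7 columns")
        mirna, gene, s_chrom, s_start, s_end, s_strand, s_cons = cols[:7]
        site = None
        if s_chrom and s_chrom != ".":
            try:
                site = GenomicInterval(s_chrom, int(s_start), int(s_end), s_strand)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
        pair = TargetPair(
            mirna, gene, site, s_cons not in ("0", "false", "False")
        )
        if pair.key() in seen:
            dupes += 1
            continue
        seen.add(pair.key())
        pairs.append(pair)
    if dupes:
        warnings.warn(f"{path}: dropped {dupes} duplicate target pair(s)")
    return pairs


def write_target_pairs(pairs: Sequence[TargetPair], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_HEADER) + "\n")
        for p in pairs:
            if p.site is not None:
                site_cols = (
                    f"{p.site.chrom}\t{p.site.start}\t{p.site.end}\t{p.site.strand}"
                )
            else:
                site_cols = ".\t.\t.\t."
            fh.write(
                f"{p.mirna}\t{p.gene}\t{site_cols}\t"
                f"{1 if p.site_conserved else 0}\n"
            )


# ---------------------------------------------------------------------------
# SNP table (TSV, 1-based position on disk)
# ---------------------------------------------------------------------------


def read_snp_table(path: PathLike) -> list[SNPRecord]:
    snps = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if cols[0] == "rsid":
            continue
        if len(cols) < 4:
            raise ParseError(path, lineno, "expected 4 columns")
        rsid, chrom, pos_s, alleles = cols[:4]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ParseError(path, lineno, f"malformed position {pos_s!r}") from None
        if pos < 1:
            raise ParseError(path, lineno, "position must be >= 1 (1-based)")
        snps.append(SNPRecord(rsid, chrom, pos - 1, alleles))
    return snps


def write_snp_table(snps: Sequence[SNPRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tposition\talleles\n")
        for s in snps:
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.position + 1}\t{s.alleles}\n")


# ---------------------------------------------------------------------------
# Network export / import (SIF, GraphML)
# ---------------------------------------------------------------------------

_VALID_NODE_KINDS = {NODE_MIRNA, NODE_TF, NODE_GENE}
_VALID_EDGE_KINDS = {EDGE_TF_GENE, EDGE_TF_MIRNA, EDGE_MIRNA_GENE, EDGE_MIRNA_TF}


def export_network(
    net: RegulatoryNetwork, path: PathLike, format: str = "sif"
) -> None:
    """Write the network as SIF (relation-labelled triples) or GraphML.

    SIF lines are ``source <tab> relation <tab> target``; isolated nodes
    are emitted as single-column lines.  GraphML carries the node ``kind``
    attribute so re-import reproduces node and edge sets exactly.
    """
    for node, data in net.graph.nodes(data=True):
        if data.get("kind") not in _VALID_NODE_KINDS:
            raise ValueError(f"node {node!r} has unknown kind {data.get('kind')!r}")
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            connected = set()
            for e in net.edges():
                fh.write(f"{e.source}\t{e.kind}\t{e.target}\n")
                connected.update((e.source, e.target))
            for node in sorted(set(net.graph.nodes) - connected):
                fh.write(f"{node}\n")
        # sidecar with node types, so SIF round-trips
        with open(str(path) + ".types", "w") as fh:
            for node in sorted(net.graph.nodes):
                fh.write(f"{node}\t{net.node_kind(node)}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for node, data in net.graph.nodes(data=True):
            g.add_node(node, kind=data["kind"])
        for u, v, data in net.graph.edges(data=True):
            g.add_edge(u, v, kind=data["kind"],
                       self_regulating=bool(data.get("self_regulating", False)))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_network(path: PathLike, format: str = "sif") -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    fmt = format.lower()
    if fmt == "sif":
        with open(str(path) + ".types") as fh:
            for line in fh:
                node, kind = line.rstrip("\n").split("\t")
                net.add_node(node, kind)
        for lineno, line in _data_lines(path):
            cols = line.split("\t")
            if len(cols) == 1:
                continue
            if len(cols) != 3:
                raise ParseError(path, lineno, "SIF lines have 1 or 3 columns")
            source, kind, target = cols
            if kind not in _VALID_EDGE_KINDS:
                raise ParseError(path, lineno, f"unknown relation {kind!r}")
            from .network import Edge

            net.add_edge(Edge(source, target, kind))
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.add_node(node, data["kind"])
        from .network import Edge

        for u, v, data in g.edges(data=True):
            net.add_edge(
                Edge(u, v, data["kind"]),
                self_regulating=bool(data.get("self_regulating", False)),
            )
    else:
        raise ValueError(f"unknown export format {format!r}")
    return net
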