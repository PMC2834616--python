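"""Regulatory-network construction: TF-group merging, motif enumeration,
network convergence and hub (core-node) detection.

The three-node feed-forward loop (FFL) is the central motif: a TF regulates
both a miRNA and a target gene (binding sites in their promoters), while the
miRNA also represses that gene.  The two-node composite feedback loop pairs
a TF that regulates a miRNA with that miRNA targeting the TF's own gene.

Redundant binding-site matrices are first merged into *TF groups*: within
one promoter, matrix placements that overlap and share a TF symbol, or that
have an identical consensus, are one binding event; across promoters the
same matrix is the same regulator.  Groups are the connected components of
this relation, and loops are counted at the (group, precursor, gene) level,
so a block of near-identical matrices never inflates motif counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

from .types import Config, GenomicInterval, MiRNARecord, TargetPair, TFBSHit

NODE_MIRNA = "mirna"
NODE_TF = "tf"
NODE_GENE = "gene"

EDGE_TF_GENE = "tf_gene"
EDGE_TF_MIRNA = "tf_mirna"
EDGE_MIRNA_GENE = "mirna_gene"
EDGE_MIRNA_TF = "mirna_tf"

OWNER_GENE = "gene"
OWNER_MIRNA = "mirna"


@dataclass(frozen=True)
class MappedHit:
    """A TFBS hit assigned to the promoter of ``owner``."""

    hit: TFBSHit
    owner: str
    owner_kind: str  # OWNER_GENE or OWNER_MIRNA


@dataclass(frozen=True)
class TFGroup:
    """A merged set of redundant TFBS matrices counted as one regulator."""

    group_id: str
    matrix_ids: frozenset[str]
    tf_symbols: frozenset[str]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    kind: str
    evidence: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FFL:
    """TF-group -> {miRNA, gene}; miRNA -> gene."""

    tf_group: TFGroup
    mirna: str
    gene: str
    evidence: frozenset[str] = frozenset()

    def sort_key(self) -> tuple[str, str, str]:
        return (self.gene, self.mirna, self.tf_group.group_id)


@dataclass(frozen=True)
class FeedbackLoop:
    """TF-group -> miRNA and miRNA -> gene encoding a symbol of the group."""

    tf_group: TFGroup
    mirna: str
    tf_gene_targeted: str

    def sort_key(self) -> tuple[str, str, str]:
        return (self.tf_gene_targeted, self.mirna, self.tf_group.group_id)


class RegulatoryNetwork:
    """Typed directed graph over miRNA, TF-group and gene nodes.

    Thin wrapper around a :class:`networkx.DiGraph`; node attribute ``kind``
    is one of {mirna, tf, gene}, edge attribute ``kind`` one of the four
    regulation types.  A gene that also encodes a TF symbol of some group
    keeps its own gene node; the coincidence is recorded on the edge as
    ``self_regulating`` and such edges are excluded from a TF's out-counts
    by default.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self.groups: dict[str, TFGroup] = {}

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in (NODE_MIRNA, NODE_TF, NODE_GENE):
            raise ValueError(f"unknown node kind {kind!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["kind"] != kind:
            raise ValueError(
                f"node {node_id!r} already typed {existing['kind']!r}, "
                f"cannot retype to {kind!r}"
            )
        self.graph.add_node(node_id, kind=kind)

    def add_edge(self, edge: Edge, self_regulating: bool = False) -> None:
        if not (
            self.graph.has_node(edge.source) and self.graph.has_node(edge.target)
        ):
            raise ValueError(f"dangling edge {edge.source} -> {edge.target}")
        if self.graph.has_edge(edge.source, edge.target):
            data = self.graph.edges[edge.source, edge.target]
            data["evidence"] = frozenset(data["evidence"] | edge.evidence)
            data["self_regulating"] = data["self_regulating"] or self_regulating
        else:
            self.graph.add_edge(
                edge.source,
                edge.target,
                kind=edge.kind,
                evidence=edge.evidence,
                self_regulating=self_regulating,
            )

    # -- queries ------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == kind
        )

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def edges(self) -> list[Edge]:
        return sorted(
            (
                Edge(u, v, d["kind"], d["evidence"])
                for u, v, d in self.graph.edges(data=True)
            ),
            key=lambda e: (e.kind, e.source, e.target),
        )

    def predecessors_of_kind(self, node_id: str, kind: str) -> set[str]:
        return {
            p
            for p in self.graph.predecessors(node_id)
            if self.graph.nodes[p]["kind"] == kind
        }

    def successors_of_kind(
        self, node_id: str, kind: str, include_self_edges: bool = True
    ) -> set[str]:
        out = set()
        for s in self.graph.successors(node_id):
            if self.graph.nodes[s]["kind"] != kind:
                continue
            if not include_self_edges and self.graph.edges[node_id, s].get(
                "self_regulating", False
            ):
                continue
            out.add(s)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data="kind"))
            == dict(other.graph.nodes(data="kind"))
            and {
                (u, v): d["kind"] for u, v, d in self.graph.edges(data=True)
            }
            == {(u, v): d["kind"] for u, v, d in other.graph.edges(data=True)}
        )


# ---------------------------------------------------------------------------
# TF-group merging
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _mergeable(a: TFBSHit, b: TFBSHit) -> bool:
    """Merge rule within one promoter."""
    if a.consensus == b.consensus:
        return True
    if a.interval.overlaps(b.interval) and set(a.tf_symbols) & set(b.tf_symbols):
        return True
    return False


def merge_tfbs_groups(
    mapped_hits: Sequence[MappedHit],
) -> tuple[dict[str, TFGroup], dict[str, str]]:
    """Merge redundant matrices into TF groups.

    Within one promoter, two placements merge when they overlap and share a
    TF symbol, or carry an identical consensus; across promoters placements
    of the same matrix are one regulator.  Returns the groups keyed by
    ``group_id`` plus the matrix_id -> group_id lookup.  ``group_id`` is the
    '+'-joined sorted tuple of member matrix ids, so identical inputs always
    produce identical labels.
    """
    uf = _UnionFind()
    by_owner: dict[tuple[str, str], list[TFBSHit]] = {}
    for mh in mapped_hits:
        uf.find(mh.hit.matrix_id)  # register even isolated matrices
        by_owner.setdefault((mh.owner_kind, mh.owner), []).append(mh.hit)
    for hits in by_owner.values():
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                if _mergeable(hits[i], hits[j]):
                    uf.union(hits[i].matrix_id, hits[j].matrix_id)

    members: dict[str, set[str]] = {}
    symbols: dict[str, set[str]] = {}
    for mh in mapped_hits:
        root = uf.find(mh.hit.matrix_id)
        members.setdefault(root, set()).add(mh.hit.matrix_id)
        symbols.setdefault(root, set()).update(mh.hit.tf_symbols)

    groups: dict[str, TFGroup] = {}
    matrix_to_group: dict[str, str] = {}
    for root, mats in members.items():
        gid = "+".join(sorted(mats))
        group = TFGroup(gid, frozenset(mats), frozenset(symbols[root]))
        groups[gid] = group
        for m in mats:
            matrix_to_group[m] = gid
    return groups, matrix_to_group


def build_tf_edges(
    mapped_hits: Sequence[MappedHit],
    matrix_to_group: dict[str, str],
) -> tuple[list[Edge], list[Edge]]:
    """Lift promoter-mapped hits to group-level tf_gene / tf_mirna edges.

    Edge evidence records the matrix ids actually placed in that promoter.
    """
    acc: dict[tuple[str, str, str], set[str]] = {}
    for mh in mapped_hits:
        gid = matrix_to_group[mh.hit.matrix_id]
        kind = EDGE_TF_GENE if mh.owner_kind == OWNER_GENE else EDGE_TF_MIRNA
        acc.setdefault((gid, mh.owner, kind), set()).add(mh.hit.matrix_id)
    tf_gene, tf_mirna = [], []
    for (gid, owner, kind), mats in sorted(acc.items()):
        edge = Edge(gid, owner, kind, frozenset(mats))
        (tf_gene if kind == EDGE_TF_GENE else tf_mirna).append(edge)
    return tf_gene, tf_mirna


# ---------------------------------------------------------------------------
# miRNA -> gene edges
# ---------------------------------------------------------------------------


def build_mirna_gene_edges(
    pairs: Sequence[TargetPair],
    mirnas: Sequence[MiRNARecord],
    cfg: Config,
) -> list[Edge]:
    """Expand mature-level target pairs to per-precursor edges.

    The conserved-site filter drops non-conserved sites, except for
    precursors of primate-specific (class P) miRNAs, whose sites cannot be
    conserved in mammals by definition.
    """
    from .types import mature_to_precursors

    expansion = mature_to_precursors(mirnas)
    conservation = {m.precursor_id: m.conservation_class for m in mirnas}
    acc: dict[tuple[str, str], set[str]] = {}
    for pair in pairs:
        if pair.mirna not in expansion:
            raise KeyError(
                f"target pair names unknown miRNA {pair.mirna!r}; "
                "no matching precursor in the annotation"
            )
        for precursor in expansion[pair.mirna]:
            if (
                cfg.require_site_conserved
                and not pair.site_conserved
                and conservation[precursor] != "P"
            ):
                continue
            site_id = (
                f"{pair.site.chrom}:{pair.site.start}-{pair.site.end}"
                if pair.site is not None
                else f"{pair.mirna}->{pair.gene}"
            )
            acc.setdefault((precursor, pair.gene), set()).add(site_id)
    return [
        Edge(precursor, gene, EDGE_MIRNA_GENE, frozenset(sites))
        for (precursor, gene), sites in sorted(acc.items())
    ]


# ---------------------------------------------------------------------------
# Motif enumeration
# ---------------------------------------------------------------------------


def find_ffls(
    tf_gene: Sequence[Edge],
    tf_mirna: Sequence[Edge],
    mirna_gene: Sequence[Edge],
    groups: dict[str, TFGroup],
) -> list[FFL]:
    """Enumerate feed-forward loops.

    One FFL per (group g, precursor m, gene t) such that g has a binding
    site in t's promoter, g has one in m's promoter, and m targets t.
    Output is deduplicated and sorted by (gene, mirna, group).
    """
    g_to_genes: dict[str, dict[str, frozenset[str]]] = {}
    for e in tf_gene:
        g_to_genes.setdefault(e.source, {})[e.target] = e.evidence
    g_to_mirnas: dict[str, dict[str, frozenset[str]]] = {}
    for e in tf_mirna:
        g_to_mirnas.setdefault(e.source, {})[e.target] = e.evidence
    m_to_genes: dict[str, dict[str, frozenset[str]]] = {}
    for e in mirna_gene:
        m_to_genes.setdefault(e.source, {})[e.target] = e.evidence

    out: dict[tuple[str, str, str], FFL] = {}
    for gid, genes in g_to_genes.items():
        mirnas = g_to_mirnas.get(gid)
        if not mirnas:
            continue
        for m, m_ev in mirnas.items():
            targets = m_to_genes.get(m)
            if not targets:
                continue
            for t, t_ev in targets.items():
                if t not in genes:
                    continue
                key = (t, m, gid)
                if key not in out:
                    out[key] = FFL(
                        groups[gid], m, t, frozenset(genes[t] | m_ev | t_ev)
                    )
    return sorted(out.values(), key=FFL.sort_key)


def find_ffls_bruteforce(
    tf_gene: Sequence[Edge],
    tf_mirna: Sequence[Edge],
    mirna_gene: Sequence[Edge],
    groups: dict[str, TFGroup],
) -> list[FFL]:
    """Triple-loop reference enumeration over all (group, mirna, gene).

    Independent oracle for :func:`find_ffls`; quadratic-cubic, use only on
    small instances.
    """
    tg = {(e.source, e.target) for e in tf_gene}
    tm = {(e.source, e.target) for e in tf_mirna}
    mg = {(e.source, e.target) for e in mirna_gene}
    all_groups = sorted({g for g, _ in tg} | {g for g, _ in tm})
    all_mirnas = sorted({m for _, m in tm} | {m for m, _ in mg})
    all_genes = sorted({t for _, t in tg} | {t for _, t in mg})
    out = []
    for t in all_genes:
        for m in all_mirnas:
            for g in all_groups:
                if (g, t) in tg and (g, m) in tm and (m, t) in mg:
                    out.append(FFL(groups[g], m, t))
    return out


def find_feedback_loops(
    tf_mirna: Sequence[Edge],
    mirna_gene_all: Sequence[Edge],
    groups: dict[str, TFGroup],
    tf_symbol_to_gene: Optional[dict[str, str]] = None,
) -> list[FeedbackLoop]:
    """Enumerate miRNA-TF mutual (composite feedback) loops.

    A loop exists per (group, precursor) where the group binds the miRNA's
    promoter and the miRNA targets a gene encoding any of the group's TF
    symbols.  ``tf_symbol_to_gene`` maps TF symbols to gene symbols when
    they differ (identity by default).
    """
    symbol_map = tf_symbol_to_gene or {}
    m_targets: dict[str, set[str]] = {}
    for e in mirna_gene_all:
        m_targets.setdefault(e.source, set()).add(e.target)
    out = []
    for e in tf_mirna:
        group = groups[e.source]
        targets = m_targets.get(e.target, set())
        for sym in sorted(group.tf_symbols):
            gene = symbol_map.get(sym, sym)
            if gene in targets:
                out.append(FeedbackLoop(group, e.target, gene))
    return sorted(set(out), key=FeedbackLoop.sort_key)


# ---------------------------------------------------------------------------
# Network convergence
# ---------------------------------------------------------------------------


def merge_network(
    ffls: Sequence[FFL],
    loops: Sequence[FeedbackLoop] = (),
) -> RegulatoryNetwork:
    """Converge FFLs and feedback loops into one regulatory network.

    All FFL nodes and edges are included.  A feedback loop enters only when
    it shares at least one TF-group or miRNA node with some FFL, so the
    network stays anchored on the FFL backbone.
    """
    net = RegulatoryNetwork()
    ffl_groups = {f.tf_group.group_id for f in ffls}
    ffl_mirnas = {f.mirna for f in ffls}
    for f in sorted(ffls, key=FFL.sort_key):
        _add_ffl(net, f)
    for lp in sorted(loops, key=FeedbackLoop.sort_key):
        if lp.tf_group.group_id in ffl_groups or lp.mirna in ffl_mirnas:
            _add_feedback(net, lp)
    return net


def _self_regulating(group: TFGroup, gene: str) -> bool:
    return gene in group.tf_symbols


def _add_ffl(net: RegulatoryNetwork, f: FFL) -> None:
    gid = f.tf_group.group_id
    net.groups[gid] = f.tf_group
    net.add_node(gid, NODE_TF)
    net.add_node(f.mirna, NODE_MIRNA)
    net.add_node(f.gene, NODE_GENE)
    net.add_edge(
        Edge(gid, f.gene, EDGE_TF_GENE, f.evidence),
        self_regulating=_self_regulating(f.tf_group, f.gene),
    )
    net.add_edge(Edge(gid, f.mirna, EDGE_TF_MIRNA, f.evidence))
    net.add_edge(Edge(f.mirna, f.gene, EDGE_MIRNA_GENE))


def _add_feedback(net: RegulatoryNetwork, lp: FeedbackLoop) -> None:
    gid = lp.tf_group.group_id
    net.groups[gid] = lp.tf_group
    net.add_node(gid, NODE_TF)
    net.add_node(lp.mirna, NODE_MIRNA)
    net.add_edge(Edge(gid, lp.mirna, EDGE_TF_MIRNA))
    # the repression arm runs back onto the TF group itself
    net.add_edge(Edge(lp.mirna, gid, EDGE_MIRNA_TF))


# ---------------------------------------------------------------------------
# Core nodes and subnetworks
# ---------------------------------------------------------------------------


def find_core_nodes(net: RegulatoryNetwork, cfg: Config) -> dict[str, list[str]]:
    """Detect hub nodes.

    A core gene is regulated by >= ``core_min_tfs`` TF groups and
    >= ``core_min_mirnas`` miRNAs; a core miRNA regulates
    >= ``core_min_targets`` genes while being regulated by
    >= ``core_min_tfs`` TF groups.  Regulator multiplicity is counted at
    the merged-group level.
    """
    core_genes = []
    for gene in net.nodes_of_kind(NODE_GENE):
        n_tf = len(net.predecessors_of_kind(gene, NODE_TF))
        n_mir = len(net.predecessors_of_kind(gene, NODE_MIRNA))
        if n_tf >= cfg.core_min_tfs and n_mir >= cfg.core_min_mirnas:
            core_genes.append(gene)
    core_mirnas = []
    for m in net.nodes_of_kind(NODE_MIRNA):
        n_targets = len(net.successors_of_kind(m, NODE_GENE))
        n_tf = len(net.predecessors_of_kind(m, NODE_TF))
        if n_targets >= cfg.core_min_targets and n_tf >= cfg.core_min_tfs:
            core_mirnas.append(m)
    return {"core_genes": sorted(core_genes), "core_mirnas": sorted(core_mirnas)}


def extract_subnetwork(net: RegulatoryNetwork, node_id: str) -> RegulatoryNetwork:
    """Induced subgraph of a node and its direct neighbours."""
    if not net.graph.has_node(node_id):
        raise KeyError(f"unknown node {node_id!r}")
    keep = (
        {node_id}
        | set(net.graph.predecessors(node_id))
        | set(net.graph.successors(node_id))
    )
    sub = RegulatoryNetwork()
    sub.graph = net.graph.subgraph(keep).copy()
    sub.groups = {g: v for g, v in net.groups.items() if g in keep}
    return sub
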