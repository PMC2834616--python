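"""End-to-end pipeline: inputs -> edges -> loops -> network -> stats -> SNPs.

Stage order matches the analysis design: promoter assignment, TFBS
filtering and edge construction, motif enumeration, network convergence
with core-node detection, enrichment statistics, SNP overlay, exports.
Each run writes a manifest recording the exact configuration, input file
digests, stage timings and output paths, so deterministic stages can be
reproduced byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as mio
from .network import (
    EDGE_MIRNA_GENE,
    Edge,
    TFGroup,
    build_mirna_gene_edges,
    build_tf_edges,
    find_core_nodes,
    find_feedback_loops,
    find_ffls,
    merge_network,
    merge_tfbs_groups,
)
from .promoters import (
    assign_gene_promoter,
    assign_mirna_promoters,
    cluster_mirnas,
    map_tfbs_to_promoters,
)
from .snp_overlay import annotate_snps, summarize_snp_annotations
from .stats import permutation_ffl_test
from .types import Config, MiRNARecord, TargetPair, mature_to_precursors


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str]
    stage_seconds: dict[str, float]
    outputs: dict[str, str]
    summary: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


INPUT_NAMES = {
    "genes": "genes.bed",
    "mirnas": "mirnas.gff3",
    "tfbs": "tfbs_track.tsv",
    "pairs": "target_pairs.tsv",
    "snps": "snps.tsv",
}
OPTIONAL_INPUTS = {
    "matrix_map": "matrix_tf_map.tsv",
    "focal_genes": "focal_genes.txt",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _expand_pairs(
    pairs: list[TargetPair], mirnas: list[MiRNARecord]
) -> list[TargetPair]:
    """Precursor-level expansion of mature/family-named pairs."""
    expansion = mature_to_precursors(mirnas)
    out, seen = [], set()
    for p in pairs:
        if p.mirna not in expansion:
            raise KeyError(f"target pair names unknown miRNA {p.mirna!r}")
        for precursor in expansion[p.mirna]:
            q = TargetPair(precursor, p.gene, p.site, p.site_conserved)
            if q.key() not in seen:
                seen.add(q.key())
                out.append(q)
    return out


def run_all(
    input_dir,
    out_dir,
    cfg: Optional[Config] = None,
    config_path=None,
) -> RunManifest:
    """Execute every stage on the five input files in ``input_dir``."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = Config.from_yaml(config_path) if config_path else Config()

    timings: dict[str, float] = {}
    digests: dict[str, str] = {}
    outputs: dict[str, str] = {}

    def _input(key: str, stage: str, optional: bool = False) -> Optional[Path]:
        name = INPUT_NAMES.get(key, OPTIONAL_INPUTS.get(key))
        path = input_dir / name
        if not path.exists():
            if optional:
                return None
            raise StageError(stage, f"missing input file {path}")
        digests[name] = _sha256(path)
        return path

    # -- load stage ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        genes = mio.read_gene_bed(_input("genes", "load"))
        mirnas = mio.read_mirna_annotation(_input("mirnas", "load"))
        pairs = mio.read_target_pairs(_input("pairs", "load"))
        snp_path = input_dir / INPUT_NAMES["snps"]
        snps = []
        if snp_path.exists():
            digests[INPUT_NAMES["snps"]] = _sha256(snp_path)
            snps = mio.read_snp_table(snp_path)
    except StageError:
        raise
    except Exception as exc:  # parse errors surface with their stage
        raise StageError("load", str(exc)) from exc
    timings["load"] = time.perf_counter() - t0

    # -- promoters stage ----------------------------------------------
    t0 = time.perf_counter()
    try:
        clusters = cluster_mirnas(mirnas, cfg)
        gene_promoters = [assign_gene_promoter(g, cfg) for g in genes]
        mirna_promoters = assign_mirna_promoters(mirnas, genes, cfg)
    except Exception as exc:
        raise StageError("promoters", str(exc)) from exc
    timings["promoters"] = time.perf_counter() - t0

    # -- edges stage ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        tfbs_path = _input("tfbs", "edges")
        map_path = _input("matrix_map", "edges", optional=True)
        tf_map = mio.read_matrix_tf_map(map_path) if map_path else None
        hits = mio.read_tfbs_track(tfbs_path, tf_map)
        mapped = map_tfbs_to_promoters(
            hits, gene_promoters + mirna_promoters, cfg
        )
        groups, matrix_to_group = merge_tfbs_groups(mapped)
        tf_gene, tf_mirna = build_tf_edges(mapped, matrix_to_group)
        mirna_gene = build_mirna_gene_edges(pairs, mirnas, cfg)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("edges", str(exc)) from exc
    timings["edges"] = time.perf_counter() - t0

    # -- loops stage ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        ffls = find_ffls(tf_gene, tf_mirna, mirna_gene, groups)
        loops = find_feedback_loops(tf_mirna, mirna_gene, groups)
    except Exception as exc:
        raise StageError("loops", str(exc)) from exc
    timings["loops"] = time.perf_counter() - t0

    # -- merge stage ----------------------------------------------------
    t0 = time.perf_counter()
    net = merge_network(ffls, loops)
    core = find_core_nodes(net, cfg)
    timings["merge"] = time.perf_counter() - t0

    # -- stats stage -----------------------------------------------------
    t0 = time.perf_counter()
    stats_row = None
    try:
        focal_path = _input("focal_genes", "stats", optional=True)
        focal = (
            {line.strip() for line in open(focal_path) if line.strip()}
            if focal_path
            else {g.symbol for g in genes}
        )
        expanded = _expand_pairs(pairs, mirnas)
        conserved = {m.precursor_id: m.conservation_class for m in mirnas}
        usable = [
            p
            for p in expanded
            if p.site_conserved
            or not cfg.require_site_conserved
            or conserved[p.mirna] == "P"
        ]
        k = sum(1 for p in usable if p.gene in focal)
        if 0 < k <= len(usable):
            res = permutation_ffl_test(
                len(ffls), usable, k, tf_gene, tf_mirna, groups, cfg
            )
            stats_row = {
                "method": res.method,
                "observed_ffls": len(ffls),
                "k": k,
                "n_pairs": len(usable),
                "reps": res.reps,
                "p_value": res.p_value,
                "null_mean": res.null_mean,
                "seed": res.seed,
            }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc
    timings["stats"] = time.perf_counter() - t0

    # -- snp stage -------------------------------------------------------
    t0 = time.perf_counter()
    annotations = annotate_snps(snps, pairs, mapped, mirnas, cfg)
    snp_summary = summarize_snp_annotations(annotations)
    timings["snp"] = time.perf_counter() - t0

    # -- export stage ----------------------------------------------------
    t0 = time.perf_counter()
    outputs["ffls"] = str(out_dir / "ffls.tsv")
    with open(outputs["ffls"], "w") as fh:
        fh.write("gene\tmirna\ttf_group\ttf_symbols\n")
        for f in ffls:
            fh.write(
                f"{f.gene}\t{f.mirna}\t{f.tf_group.group_id}\t"
                f"{','.join(sorted(f.tf_group.tf_symbols))}\n"
            )
    outputs["feedback_loops"] = str(out_dir / "feedback_loops.tsv")
    with open(outputs["feedback_loops"], "w") as fh:
        fh.write("tf_group\tmirna\ttf_gene_targeted\n")
        for lp in loops:
            fh.write(
                f"{lp.tf_group.group_id}\t{lp.mirna}\t{lp.tf_gene_targeted}\n"
            )
    outputs["core_nodes"] = str(out_dir / "core_nodes.tsv")
    with open(outputs["core_nodes"], "w") as fh:
        fh.write("node\trole\n")
        for g in core["core_genes"]:
            fh.write(f"{g}\tcore_gene\n")
        for m in core["core_mirnas"]:
            fh.write(f"{m}\tcore_mirna\n")
    outputs["network_sif"] = str(out_dir / "network.sif")
    mio.export_network(net, outputs["network_sif"], "sif")
    outputs["network_graphml"] = str(out_dir / "network.graphml")
    mio.export_network(net, outputs["network_graphml"], "graphml")
    outputs["snp_annotations"] = str(out_dir / "snp_annotations.tsv")
    with open(outputs["snp_annotations"], "w") as fh:
        fh.write("rsid\tcategory\telements\n")
        for ann in annotations:
            for cat in sorted(ann.categories):
                fh.write(
                    f"{ann.rsid}\t{cat}\t{','.join(ann.elements.get(cat, []))}\n"
                )
    if stats_row is not None:
        outputs["stats"] = str(out_dir / "stats.tsv")
        with open(outputs["stats"], "w") as fh:
            fh.write("\t".join(stats_row) + "\n")
            fh.write("\t".join(str(v) for v in stats_row.values()) + "\n")
    timings["export"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.rng_seed,
        input_digests=digests,
        stage_seconds={k: round(v, 6) for k, v in timings.items()},
        outputs=outputs,
        summary={
            "n_genes": len(genes),
            "n_mirnas": len(mirnas),
            "n_clusters_multi": sum(1 for c in clusters if len(c.members) > 1),
            "n_mapped_hits": len(mapped),
            "n_tf_groups": len(groups),
            "n_ffls": len(ffls),
            "n_feedback_loops": len(loops),
            "core_genes": core["core_genes"],
            "core_mirnas": core["core_mirnas"],
            "snp_summary": snp_summary,
            "permutation": stats_row,
        },
    )
    manifest.write(out_dir / "run_manifest.json")
    return manifest
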