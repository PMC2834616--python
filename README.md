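# mirtfnet

Combinatorial gene regulation by microRNAs and transcription factors,
analysed as a network-motif problem. `mirtfnet` builds the three
regulatory edge sets implied by standard annotation inputs —

* **TF → gene**: a conserved binding-site matrix hit in a gene's promoter,
* **TF → miRNA**: the same, in the promoter of a miRNA precursor, its
  genomic cluster, or its host gene,
* **miRNA → gene**: a conserved 3'UTR target-site prediction,

— and then enumerates the two composite motifs that couple transcriptional
and post-transcriptional control:

* the **feed-forward loop (FFL)**: TF → miRNA, TF → gene, miRNA ⊣ gene,
* the **mutual feedback loop**: TF → miRNA, miRNA ⊣ (gene encoding that TF).

Loops are converged into a typed regulatory network, hub ("core") nodes
are detected by degree thresholds, and enrichment of the observed FFL
yield is evaluated with Fisher's exact test and a resampling null that
redraws target pairs and recounts loops. A SNP overlay categorises
variants falling on target sites, binding sites, pre-miRNA hairpins and
their flanks. The package is aimed at anyone studying miRNA–TF
co-regulation of a disease gene set from desk-scale annotation tables.

## The model in brief

Promoters are fixed windows (default 5 kb) strand-aware upstream of a TSS,
precursor, cluster span, or host gene; precursors within 5 kb of each other
on one strand are treated as one transcription unit. Binding-site hits are
retained when their track Z score exceeds 2.33 (strict) and the placement
is conserved in human/mouse/rat. Redundant matrices are merged into *TF
groups* (overlapping placement with a shared TF symbol, or identical
consensus; the same matrix is one regulator across promoters), and all
motif counting is done at the (TF group, precursor, gene) level. A core
gene is regulated by ≥ 3 TF groups and ≥ 3 miRNAs; a core miRNA regulates
≥ 3 genes while being regulated by ≥ 3 TF groups. FFL enrichment between
two miRNA sets is a two-sided Fisher test on `[[FFLs_A, n_A], [FFLs_B,
n_B]]`; the resampling test redraws the same number of target pairs from
the full prediction table 10,000 times and reports the proportion of
replicates reaching the observed loop count.

## Worked example

The package ships a reference fixture set: 29 schizophrenia-associated
miRNA precursors with coordinates and conservation classes, and the 32
published TF–miRNA–gene loops among them. Rebuilding the network from the
matrix-level edge sets:

```python
from mirtfnet import table2_edge_bundle, Config
from mirtfnet.network import (merge_tfbs_groups, build_tf_edges, find_ffls,
                              merge_network, find_core_nodes)
from mirtfnet.stats import ffl_set_comparison

bundle = table2_edge_bundle()
groups, m2g = merge_tfbs_groups(bundle.mapped_hits)
tf_gene, tf_mirna = build_tf_edges(bundle.mapped_hits, m2g)
ffls = find_ffls(tf_gene, tf_mirna, bundle.mirna_gene_edges, groups)
net = merge_network(ffls)
core = find_core_nodes(net, Config())
print(f"FFLs: {len(ffls)}")
print(f"gene nodes: {len(net.nodes_of_kind('gene'))}")
print(f"core genes: {core['core_genes']}")
print(f"core miRNAs: {core['core_mirnas']}")
res = ffl_set_comparison(32, 29, 24, 94)
print(f"disease vs non-brain miRNAs: odds={res.odds_ratio:.2f} p={res.p_value:.2e}")
```

prints

```
FFLs: 32
gene nodes: 16
core genes: ['EGR3', 'GRM7']
core miRNAs: ['hsa-miR-195', 'hsa-miR-20b', 'hsa-miR-9-3']
disease vs non-brain miRNAs: odds=4.32 p=1.80e-05
```

The 32 enumerated loops span 16 candidate genes; five hub nodes emerge,
with the zinc-finger factor EGR3 (regulated by 5 TF groups and 4 miRNAs,
itself regulating 3 genes and 3 miRNAs through the EGR matrix group) and
hsa-miR-195 (repressing 6 of the 16 genes) as the central regulators. The
Fisher comparison says the disease miRNA set yields about four times more
loops per miRNA than non-brain-expressed miRNAs (p ≈ 2 × 10⁻⁵).

## Command line

```bash
mirtfnet simulate --seed 11 --out bundle/        # synthetic inputs, planted truth
mirtfnet run-all --input-dir bundle/ --out run/  # full pipeline + manifest
mirtfnet enrich --ffl-a 32 --n-a 29 --ffl-b 24 --n-b 94
```

`run-all` writes loop tables, a core-node report, SIF/GraphML network
exports, SNP annotations, the resampling-test result and a reproducibility
manifest (config snapshot, input digests, stage timings).

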