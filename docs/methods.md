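# Methods

## Coordinates

All intervals are stored 0-based half-open; 1-based inclusive dialects
(GFF3, display-style locations) and 1-based SNP positions are converted at
the I/O boundary only. This keeps every piece of promoter and overlap
arithmetic in one convention. The inter-precursor gap used for clustering
is `next.start − prev.end` in the internal convention, i.e. the number of
bases strictly between the two hairpins.

## Promoters and clustering

A promoter is a fixed-length window immediately 5' of its basis feature,
computed strand-aware (on the minus strand "upstream" is
coordinate-increasing). Defaults: 5,000 bp for genes and for miRNAs
(`gene_promoter_len`, `mirna_promoter_len`). The gene-promoter length is a
package default rather than an external convention — the miRNA rule is
mirrored, and loop results are robust down to 1 kb windows, which the
configuration exposes. Windows that would cross coordinate 0 are truncated
with a warning.

Precursors chain into clusters by single-linkage when consecutive
same-chromosome gaps are ≤ `cluster_max_gap` (5 kb). Clustering requires a
shared strand by default (`cluster_same_strand`) because a shared
transcription unit implies one orientation; this is configurable.
Promoter precedence per precursor: cluster window (upstream of the full
span) over host-gene window over own-hairpin window
(`cluster_promoter_wins`). Host-gene promoters apply to intronic and
3'UTR-hosted precursors only; an antisense "host" does not share a
transcription unit, so those precursors are treated as intergenic
(`antisense_host_as_intergenic`).

## Binding-site retention and TF groups

A track hit is retained when its Z score is strictly greater than
`z_cutoff` (2.33, the one-sided 1% normal quantile) and, by default, the
placement is conserved across human/mouse/rat; retention requires ≥ 1 bp
of overlap with a promoter window, and a hit spanning two windows counts
for both owners. Overlap queries go through an interval tree; an all-pairs
scan is kept as a test oracle.

Redundant matrices are merged into TF groups by the transitive closure of
two relations: within one promoter, (a) overlapping placement with at
least one shared TF symbol, or (b) identical consensus string; and across
promoters, identity of the matrix id (the same matrix is the same
regulator wherever it binds). Groups are therefore global connected
components, labelled by the sorted '+'-joined member matrices. All loop
enumeration and degree counting uses groups, not individual matrices or
symbols: a block of near-identical matrices stacked on one promoter is one
regulator, so motif counts are not inflated by catalog redundancy.
Disabling merging (every matrix its own group) can only increase the FFL
count; the suite asserts this monotonicity.

## Target edges

Target predictions are named at the mature/family level and expanded to
one edge per precursor of the family (families are grouped by the
annotation's family field; a trailing all-digit token in a precursor name
is a duplicate-locus index only when the preceding token already carries
the family number, so `miR-9-1` folds into `miR-9` while `miR-195` stays
itself). Non-conserved target sites are dropped unless the precursor is
primate-specific (conservation class P), whose sites cannot be conserved
in mammals by definition. Duplicate (miRNA, gene, site) rows are dropped
at ingest with a counted warning.

## Motif enumeration and the network

An FFL is a triple (TF group g, precursor m, gene t) with g → t, g → m and
m ⊣ t all present; a mutual feedback loop is a pair (g, m) where g → m and
m targets a gene encoding one of g's symbols. Enumeration is by hash join,
deduplicated, and emitted in lexicographic (gene, precursor, group) order;
a brute-force triple loop serves as the oracle on small instances.

The converged network keeps all FFL nodes and edges and admits a feedback
loop only when it shares a TF group or miRNA with some FFL, so the graph
stays anchored on the FFL backbone. A gene that also encodes a TF symbol
of some group (e.g. a zinc-finger factor whose own promoter carries its
family's matrix) keeps a single gene node; the coincidence is flagged on
the TF→gene edge as self-regulation, and such edges are excluded from the
TF's out-degree counts by default (`count_self_edges`) while still
counting toward the gene's in-degree — matching how a regulator's "genes
regulated" is normally reported.

Core genes require in-degree ≥ 3 from TF groups and ≥ 3 from miRNAs; core
miRNAs require out-degree ≥ 3 to genes and in-degree ≥ 3 from TF groups
(`core_min_tfs`, `core_min_mirnas`, `core_min_targets`). Counting at group
level rather than symbol level is deliberate: symbol-level counting would
double-count multi-symbol matrices (a single EGR-family matrix maps to
four symbols).

## Statistics

*Fisher comparison.* Two miRNA sets evaluated against the same gene list
are compared on the 2×2 table `[[FFLs_A, n_A], [FFLs_B, n_B]]`, two-sided.
The contingency construction treats the set size as the exposure; the
table builder is a single function and can be swapped.

*Resampling null for FFL yield.* Each replicate draws the observed number
of focal target pairs uniformly without replacement from the full
prediction table, rebuilds miRNA→gene edges, and recounts FFLs against the
fixed TF edges; p is the proportion of replicates reaching at least the
observed count (`r/N`; the conservative `(r+1)/(N+1)` variant is a config
option). Because TF edges are fixed, each (miRNA, gene) relation has a
constant loop contribution, so replicates reduce to subset sums and are
vectorised; duplicate relations (several sites for one pair) count once.
Default 10,000 replicates, seeded via `Config.rng_seed`; identical seeds
give bit-identical results.

*Per-miRNA target-count test.* The null distribution of target counts in
random gene sets of the focal size (drawn without replacement from the
gene universe) is compared with the observed focal count by one-sample
t-test, with the empirical quantile and direction reported alongside; a
zero-variance null falls back to the empirical quantile with a warning.
Per-miRNA results are reported without multiple-testing correction, with
an optional Benjamini–Hochberg column available downstream.

*3'UTR length guard.* A two-sided rank-sum (Mann–Whitney) comparison of
UTR lengths between the focal and background gene sets, to exclude the
trivial explanation that focal genes simply offer longer targets.

## Synthetic data

The generator lays out 2–4 synthetic chromosomes with genes on 100-kb
blocks, precursors in separate coordinate bands (a configurable fraction
genic inside host genes, a fraction in 2-member 2.1-kb clusters), a matrix
catalog with unique consensus strings, and plants FFLs and feedback loops
with dedicated matrices and disjoint gene pools (loop targets, TF-coding
genes, hosts, decoy-pair genes). Planted hits always pass retention
(Z ∈ [2.5, 4], conserved, inside the computed promoter window); decoys
each fail exactly one criterion — non-conserved, sub-threshold Z drawn
from N(1.5, 0.5²), or placed on a feature-free chromosome — and a decoy
whose Z draw happens to clear the cutoff is demoted to non-conserved and
counted in the manifest rather than silently shifting the truth. Defaults
(40 genes, 12 precursors, 7 FFLs, 4 feedback loops, ~2 decoy hits per
promoter, 30% non-conserved decoy pairs) keep every stage exercised while
the full pipeline runs in well under a second.

What the generator does *not* emulate: sequence content, overlapping real
promoter architecture, correlated decoys, or prediction-tool error
structure. Passing the planted-recovery suite shows the machinery is
correct on unambiguous inputs; it says nothing about the false-positive
rate of upstream predictions on real genomes.

## Fixtures and reproduced quantities

The bundled fixture tables carry the 29 disease-associated precursors
(with a 9-member Drosophila-conserved class), the 32 reference loops, and
the FFL counts of the three miRNA sets across four gene lists. Because the
source table prints no binding-site coordinates, the edge-bundle builder
synthesises placements: matrices listed together in one row (already
merged upstream) are placed overlapping; matrices from different rows get
disjoint slots. Rebuilding the network from these matrix-level edges
reproduces the published counts exactly: 32 loops over 16 genes and 11
precursors, five core nodes, EGR3 in-degrees of 5 groups and 4 precursors,
EGR out-degrees of 3 genes (self-edge excluded) and 3 precursors, and 6
genes repressed by hsa-miR-195. The three Fisher p-values recompute to
printed precision (1.80 × 10⁻⁵, 0.020, 9.86 × 10⁻³). One fixture p-value
(non-brain set, 270-gene list, printed 2.97 × 10⁻⁷) disagrees with the
exact test by a factor of ten with an identical mantissa; the fixture
stores the printed string, and the computed value is 2.97 × 10⁻⁶.

Quantities that depend on genome-scale prediction corpora (total TFBS
tallies, genome-wide mutual-loop and SNP counts, the full-corpus
resampling p) are out of desk-scale reach and are covered instead by the
planted-recovery, oracle-equivalence and calibration suites. The
calibration test checks that on null data the resampling p-value is
approximately uniform (type-I error at nominal 0.05 within binomial noise
over 200 independent datasets of 2,000 replicates each); the inclusive
tie-handling of the `r/N` definition makes the test conservative on
heavily discrete nulls, so the calibration scenario uses a contribution
spectrum rich enough for the grid to resolve the 5% tail.

## SNP overlay

Single-base overlap against four element classes plus a flank class;
positions are ingested 1-based and converted. The pre-miRNA flank is
`snp_flank` bp (default 100) on each side, boundary-inclusive at exactly
the limit; body and flank are mutually exclusive per precursor, and a SNP
may carry several categories across classes. Summaries report both SNP
counts and distinct owner features per category.

## Known limitations

* TF groups are formed greedily by transitive closure; a promiscuous
  matrix appearing in many promoters can chain otherwise distinct
  regulators into one group. The fixture data does not trigger this, but
  pathological catalogs could.
* Promoter windows are fixed-length and TSS-anchored; alternative
  promoters and CpG/TATA structure are out of scope.
* The feedback-loop arm maps TF symbols to gene symbols by identity unless
  an explicit mapping is supplied.
* The resampling null redraws target pairs only; TF edges are treated as
  fixed, as in the procedure it implements.
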