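"""Enrichment statistics for FFL yield and miRNA targeting.

Three procedures assess whether the motifs found in a disease gene set
exceed chance expectation:

* a two-sided Fisher's exact test comparing the FFL yield of two miRNA
  sets of different sizes (table ``[[ffl_a, n_a], [ffl_b, n_b]]``),
* a resampling null in which the same number of miRNA target pairs is
  drawn at random from the full prediction table and FFLs are recounted
  against the fixed TF edges, and
* a per-miRNA comparison of target counts in the focal gene set against
  counts in random gene sets of equal size (one-sample t-test of the null
  draws against the observed count).

A rank-sum comparison of 3'UTR lengths guards against the trivial
explanation that the focal genes simply offer more sequence to hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .network import Edge, TFGroup, find_ffls
from .types import Config, TargetPair


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]] | None
    odds_ratio: float | None
    p_value: float
    method: str
    reps: int = 0
    seed: int = 0
    observed: float | None = None
    null_mean: float | None = None
    direction: str | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def ffl_set_comparison(
    ffl_a: int, n_mirna_a: int, ffl_b: int, n_mirna_b: int
) -> EnrichmentResult:
    """Two-sided Fisher's exact test on ``[[ffl_a, n_a], [ffl_b, n_b]]``.

    Compares the FFL yield per miRNA between two miRNA sets evaluated
    against the same gene list.
    """
    table = ((ffl_a, n_mirna_a), (ffl_b, n_mirna_b))
    if any(c < 0 for row in table for c in row):
        raise ValueError("counts must be >= 0")
    if sum(c for row in table for c in row) == 0:
        raise ValueError("all-zero contingency table: test undefined")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        table=table, odds_ratio=float(odds), p_value=float(p),
        method="fisher_two_sided",
    )


def permutation_ffl_test(
    observed_ffls: int,
    all_pairs: Sequence[TargetPair],
    k: int,
    tf_gene: Sequence[Edge],
    tf_mirna: Sequence[Edge],
    groups: dict[str, TFGroup],
    cfg: Config,
) -> EnrichmentResult:
    """Resampling null for the observed FFL count.

    Each of ``cfg.permutation_reps`` replicates draws ``k`` target pairs
    uniformly without replacement from ``all_pairs``, rebuilds the
    miRNA->gene edges, recounts FFLs against the fixed TF edges, and the
    p-value is the proportion of replicates reaching at least the observed
    count (the ``(r+1)/(N+1)`` variant when
    ``cfg.conservative_permutation_p`` is set).

    Pairs here are taken at face value (already precursor-level and
    filtered); each distinct (mirna, gene) relation counts once however
    many sites support it.
    """
    if k > len(all_pairs):
        raise ValueError(f"k={k} exceeds the {len(all_pairs)} available pairs")
    rng = np.random.default_rng(cfg.rng_seed)
    reps = cfg.permutation_reps

    # Per-pair FFL contribution: c(m, t) = number of groups binding both
    # the gene's and the miRNA's promoter.  The FFL count of a sample is
    # the sum of c over its distinct (m, t) relations.
    g_genes: dict[str, set[str]] = {}
    for e in tf_gene:
        g_genes.setdefault(e.source, set()).add(e.target)
    m_groups: dict[str, set[str]] = {}
    for e in tf_mirna:
        m_groups.setdefault(e.target, set()).add(e.source)

    edge_keys = [(p.mirna, p.gene) for p in all_pairs]
    contrib = np.array(
        [
            sum(1 for g in m_groups.get(m, ()) if t in g_genes.get(g, ()))
            for m, t in edge_keys
        ],
        dtype=np.int64,
    )
    unique_edges = len(set(edge_keys)) == len(edge_keys)

    n = len(all_pairs)
    counts = np.empty(reps, dtype=np.int64)
    if unique_edges:
        # vectorised: pick k of n per replicate via argpartition of noise
        noise = rng.random((reps, n))
        idx = np.argpartition(noise, k - 1, axis=1)[:, :k]
        counts = contrib[idx].sum(axis=1)
    else:
        edge_ids = {e: i for i, e in enumerate(sorted(set(edge_keys)))}
        ids = np.array([edge_ids[e] for e in edge_keys])
        per_edge = np.zeros(len(edge_ids), dtype=np.int64)
        for e, i in edge_ids.items():
            per_edge[i] = contrib[edge_keys.index(e)]
        for r in range(reps):
            sample = rng.choice(n, size=k, replace=False)
            counts[r] = per_edge[np.unique(ids[sample])].sum()

    hits = int(np.count_nonzero(counts >= observed_ffls))
    if cfg.conservative_permutation_p:
        p = (hits + 1) / (reps + 1)
    else:
        p = hits / reps
    return EnrichmentResult(
        table=None, odds_ratio=None, p_value=float(p), method="permutation",
        reps=reps, seed=cfg.rng_seed, observed=float(observed_ffls),
        null_mean=float(counts.mean()),
    )


def target_count_enrichment(
    mirna: str,
    focal_genes: set[str],
    universe: set[str],
    pairs: Sequence[TargetPair],
    cfg: Config,
) -> EnrichmentResult:
    """Does a miRNA hit more targets in the focal set than in random sets?

    Builds the null distribution of per-draw target counts over
    ``cfg.permutation_reps`` random gene sets of size ``len(focal_genes)``
    drawn uniformly without replacement from the universe, then applies a
    one-sample t-test of the null draws against the observed focal count.
    A zero-variance null falls back to the empirical quantile with a
    warning recorded on the result.
    """
    if len(focal_genes) > len(universe):
        raise ValueError("focal set larger than universe")
    targets = {p.gene for p in pairs if p.mirna == mirna}
    observed = len(targets & focal_genes)

    rng = np.random.default_rng(cfg.rng_seed)
    universe_arr = np.array(sorted(universe))
    is_target = np.isin(universe_arr, sorted(targets))
    reps = cfg.permutation_reps
    draws = np.empty(reps, dtype=np.int64)
    size = len(focal_genes)
    for r in range(reps):
        idx = rng.choice(len(universe_arr), size=size, replace=False)
        draws[r] = int(is_target[idx].sum())

    quantile = float(np.mean(draws < observed))
    direction = "more" if observed > draws.mean() else (
        "fewer" if observed < draws.mean() else "equal")
    if np.all(draws == draws[0]):
        # degenerate null: every draw identical
        p = float(np.mean(draws >= observed)) if direction == "more" else 1.0
        if observed == draws[0]:
            p = 1.0
        return EnrichmentResult(
            table=None, odds_ratio=None, p_value=p, method="t_test",
            reps=reps, seed=cfg.rng_seed, observed=float(observed),
            null_mean=float(draws.mean()), direction=direction,
            warning="zero-variance null; empirical quantile reported",
        )
    t_res = sps.ttest_1samp(draws, observed)
    return EnrichmentResult(
        table=None, odds_ratio=None, p_value=float(t_res.pvalue),
        method="t_test", reps=reps, seed=cfg.rng_seed,
        observed=float(observed), null_mean=float(draws.mean()),
        direction=direction,
    )


def utr_length_test(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> EnrichmentResult:
    """Two-sided rank-sum (Wilcoxon/Mann-Whitney) comparison of 3'UTR
    length distributions."""
    if len(lengths_a) == 0 or len(lengths_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(lengths_a, lengths_b, alternative="two-sided")
    return EnrichmentResult(
        table=None, odds_ratio=None, p_value=float(res.pvalue),
        method="wilcoxon",
    )
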