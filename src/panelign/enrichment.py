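"""Gene-set enrichment: hypergeometric over-representation and weighted-KS GSEA.

Over-representation uses the exact upper-tail hypergeometric probability
P(X >= overlap) for each set, with Bonferroni (used for ranking, matching
pathway-annotation practice) and BH columns.  Consensus-cluster annotation
runs this on a cluster's gene union and emits the top-ranked terms while
suppressing near-duplicates (Jaccard >= 0.5 with an already-emitted set).

GSEA follows the classic weighted running-sum statistic: with genes ranked
by logFC descending, hits add |logFC|^w normalized by the total hit weight
and misses subtract 1/(N - set size); the enrichment score is the running
sum's extremum.  The null is built from gene-label permutations at a fixed
seed, NES divides ES by the mean |null ES| of the same sign, and the
permutation p-value uses +1 smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .io_model import GeneSetCollection, LogFCTable

DEFAULT_JACCARD_SUPPRESS = 0.5


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    bonferroni_p: float
    bh_p: float


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    bh_p: float
    n_perm: int
    seed: int


def hypergeometric_enrichment(query: set[str],
                              collection: GeneSetCollection
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of a query set against each gene set."""
    stray = set(query) - collection.universe
    if stray:
        raise ContractError(
            f"query gene(s) outside the universe: {sorted(stray)[:5]}")
    M = len(collection.universe)
    N = len(query)
    names = sorted(collection.sets)
    raw = []
    for name in names:
        gs = collection.sets[name]
        k = len(query & gs)
        # P(X >= k) with X ~ Hypergeom(M, |set|, |query|)
        p = float(stats.hypergeom.sf(k - 1, M, len(gs), N))
        raw.append((name, k, len(gs), min(1.0, p)))
    n_sets = len(names)
    bh = multipletests([r[3] for r in raw], method="fdr_bh")[1] if raw else []
    results = [EnrichmentResult(
        set_name=name, overlap=k, set_size=sz, query_size=N,
        universe_size=M, p=p, bonferroni_p=min(1.0, p * n_sets),
        bh_p=float(q))
        for (name, k, sz, p), q in zip(raw, bh)]
    results.sort(key=lambda r: (r.bonferroni_p, r.set_name))
    return results


def annotate_cluster(cluster_genes: set[str],
                     collection: GeneSetCollection,
                     alpha: float = 0.05,
                     jaccard_threshold: float = DEFAULT_JACCARD_SUPPRESS
                     ) -> list[str]:
    """Annotate a consensus cluster by its top non-overlapping enriched terms.

    Terms are ranked by Bonferroni-corrected p; a term sharing >= 50% genes
    (Jaccard) with an already-emitted term is suppressed.  The first emitted
    label is the cluster annotation; empty (with a warning) when nothing is
    significant at Bonferroni ``alpha``.
    """
    query = set(cluster_genes) & collection.universe
    results = hypergeometric_enrichment(query, collection)
    labels: list[str] = []
    emitted: list[frozenset[str]] = []
    for res in results:
        if res.bonferroni_p >= alpha:
            continue
        gs = collection.sets[res.set_name]
        if any(len(gs & prev) / len(gs | prev) >= jaccard_threshold
               for prev in emitted):
            continue
        labels.append(res.set_name)
        emitted.append(gs)
    if not labels:
        warnings.warn(
            f"no gene set significant at Bonferroni {alpha}; "
            f"cluster left unannotated", stacklevel=2)
    return labels


def _running_sum_es(order: np.ndarray, weights: np.ndarray,
                    is_hit: np.ndarray) -> float:
    """ES of one ranked list: extremum of the weighted running sum."""
    n = len(order)
    nh = int(is_hit.sum())
    hit_w = np.where(is_hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit weights zero (all-zero logFCs): fall back to equal weights
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    dec = 1.0 / (n - nh)
    running = np.cumsum(np.where(is_hit, inc, -dec))
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea(ranked: LogFCTable, gene_set: set[str], weight_p: float = 1.0,
         n_perm: int = 1000, seed: int = 0,
         set_name: str = "set") -> GseaResult:
    """Weighted-KS gene set enrichment of one set against a ranked list."""
    if n_perm < 100:
        raise ContractError(f"n_perm must be >= 100, got {n_perm}")
    tab = ranked.table.copy()
    tab = tab.sort_values(["logfc"], ascending=False,
                          kind="mergesort")
    # deterministic tie-break by gene id
    tab = tab.iloc[np.lexsort((tab.index.to_numpy(),
                               -tab["logfc"].to_numpy()))]
    genes = tab.index.to_numpy()
    logfc = tab["logfc"].to_numpy(dtype=float)
    is_hit = np.isin(genes, sorted(gene_set))
    nh = int(is_hit.sum())
    if nh == 0:
        raise ContractError(f"gene set {set_name!r} has no gene in the ranked list")
    if nh == len(genes):
        raise ContractError(
            f"gene set {set_name!r} covers the whole ranked list; "
            f"no misses definable")
    weights = np.abs(logfc) ** weight_p
    es = _running_sum_es(np.arange(len(genes)), weights, is_hit)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_hits = np.zeros(len(genes), dtype=bool)
        perm_hits[rng.choice(len(genes), size=nh, replace=False)] = True
        null[b] = _running_sum_es(np.arange(len(genes)), weights, perm_hits)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same):
        nes = es / np.abs(same).mean()
        p = (np.sum(np.abs(same) >= abs(es)) + 1) / (len(same) + 1)
    else:
        nes = 0.0
        p = 1.0 / (n_perm + 1)
    return GseaResult(set_name=set_name, es=es, nes=float(nes), p=float(p),
                      bh_p=float(p), n_perm=n_perm, seed=seed)


def gsea_collection(ranked: LogFCTable, collection: GeneSetCollection,
                    weight_p: float = 1.0, n_perm: int = 1000,
                    seed: int = 0) -> list[GseaResult]:
    """GSEA over every set in a collection, BH-adjusted across sets."""
    results = []
    for name in sorted(collection.sets):
        gs = collection.sets[name] & set(ranked.genes)
        if not gs or len(gs) == len(ranked.genes):
            continue
        results.append(gsea(ranked, gs, weight_p=weight_p, n_perm=n_perm,
                            seed=seed, set_name=name))
    if results:
        bh = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [GseaResult(set_name=r.set_name, es=r.es, nes=r.nes,
                              p=r.p, bh_p=float(q), n_perm=r.n_perm,
                              seed=r.seed)
                   for r, q in zip(results, bh)]
    return results
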