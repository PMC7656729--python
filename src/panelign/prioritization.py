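"""PCA-weighted gene ranking within co-expression modules and panel assembly.

Genes are ranked inside each human module by how strongly they track the
module's dominant expression components: for gene *g* the score is

    s_g = | sum_k r_gk * ve_k |,   k = 1..5

where ``r_gk`` is the Pearson correlation of the gene's expression vector
with the sample scores of principal component *k* of the standardized module
submatrix, and ``ve_k`` is the fraction of total variance that component
explains.  High-scoring genes are the module's best single-gene surrogates.
The ranked lists are filtered to expressed one-to-one mouse orthologs, the
top fraction of each module is selected, and the union is assembled into a
capacity-bounded panel together with housekeeping and drug-target genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError, InsufficientDataError
from .io_model import (CoexpressionModule, ExpressionMatrix, OrthologyTable,
                       PanelDefinition, PanelEntry)

DEFAULT_N_COMPONENTS = 5
DEFAULT_TOP_FRACTION = 0.05
DEFAULT_TPM_THRESHOLD = 1.0
DEFAULT_CAPACITY = 770


@dataclass(frozen=True)
class ModulePCA:
    """Principal components of one module's standardized submatrix."""

    module_id: str
    component_scores: np.ndarray   # (n_samples, K) sample scores per component
    variance_fractions: np.ndarray  # (K,) fractions of *total* variance
    genes: tuple[str, ...]          # module genes used, in submatrix order

    def __post_init__(self) -> None:
        if self.variance_fractions.sum() > 1.0 + 1e-9:
            raise ContractError("variance fractions exceed 1")


@dataclass(frozen=True)
class GeneScore:
    gene: str
    module_id: str
    score: float


def _module_submatrix(expr: ExpressionMatrix,
                      module: CoexpressionModule) -> pd.DataFrame:
    present = [g for g in expr.genes if g in module.members]
    return expr.values.loc[present]


def module_pca(expr: ExpressionMatrix, module: CoexpressionModule,
               n_components: int = DEFAULT_N_COMPONENTS) -> ModulePCA:
    """PCA of a module submatrix: samples are observations, genes variables.

    Genes are centered and scaled to unit variance before the decomposition;
    constant genes are dropped (they carry no co-expression signal).
    Variance fractions are relative to the total variance of the standardized
    submatrix.  Each component's sample-score vector is oriented so that its
    largest-magnitude gene loading is positive, making correlations
    reproducible across linear-algebra backends.
    """
    if expr.unit not in ("tpm", "normalized", "log_normalized"):
        raise ContractError(f"module PCA requires normalized units, got {expr.unit!r}")
    sub = _module_submatrix(expr, module)
    X = sub.to_numpy(dtype=float).T  # samples × genes
    if X.shape[0] < 3:
        raise InsufficientDataError(
            f"module {module.module_id!r}: {X.shape[0]} samples (< 3)")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        if X.shape[1] >= 2:
            raise DegenerateInputError(
                f"module {module.module_id!r}: submatrix is constant")
        raise InsufficientDataError(
            f"module {module.module_id!r}: {int(keep.sum())} usable genes (< 2)")
    genes = tuple(g for g, k in zip(sub.index, keep) if k)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the standardized matrix; total variance = n_genes (unit-scaled).
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n = Z.shape[0]
    k = min(n_components, len(S))
    eigvals = S**2 / (n - 1)
    total_var = Z.shape[1]
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):
        imax = np.argmax(np.abs(loadings[:, j]))
        if loadings[imax, j] < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    ve = np.zeros(n_components)
    ve[:k] = eigvals[:k] / total_var
    full_scores = np.zeros((n, n_components))
    full_scores[:, :k] = scores
    return ModulePCA(module_id=module.module_id,
                     component_scores=full_scores,
                     variance_fractions=ve,
                     genes=genes)


def gene_ranking_scores(expr: ExpressionMatrix, pca: ModulePCA,
                        module: CoexpressionModule,
                        variant: str = "abs-of-sum") -> list[GeneScore]:
    """Score every module gene and return scores sorted descending.

    ``variant`` selects the aggregation: ``abs-of-sum`` (default) is
    ``|sum_k r_gk * ve_k|``; ``sum-of-abs`` is ``sum_k |r_gk * ve_k|``.
    Constant genes score 0.  Ties break by gene identifier ascending.
    """
    if pca.module_id != module.module_id:
        raise ContractError(
            f"PCA for module {pca.module_id!r} used with module "
            f"{module.module_id!r}")
    if variant not in ("abs-of-sum", "sum-of-abs"):
        raise ContractError(f"unknown scoring variant {variant!r}")
    sub = _module_submatrix(expr, module)
    X = sub.to_numpy(dtype=float)
    scores = []
    pcs = pca.component_scores
    ve = pca.variance_fractions
    pc_sd = pcs.std(axis=0, ddof=1)
    pcs_c = pcs - pcs.mean(axis=0)
    n = pcs.shape[0]
    for gene, row in zip(sub.index, X):
        sd = row.std(ddof=1)
        if sd == 0:
            scores.append(GeneScore(gene=gene, module_id=module.module_id,
                                    score=0.0))
            continue
        rc = row - row.mean()
        r = np.zeros(len(ve))
        for j in range(len(ve)):
            if pc_sd[j] > 0:
                r[j] = (rc @ pcs_c[:, j]) / ((n - 1) * sd * pc_sd[j])
        if variant == "abs-of-sum":
            s = abs(float(np.dot(r, ve)))
        else:
            s = float(np.sum(np.abs(r * ve)))
        scores.append(GeneScore(gene=gene, module_id=module.module_id, score=s))
    scores.sort(key=lambda gs: (-gs.score, gs.gene))
    return scores


def mean_tpm(mouse_expr: ExpressionMatrix) -> pd.Series:
    """Per-gene mean TPM across the reference samples."""
    if mouse_expr.unit != "tpm":
        raise ContractError(
            f"expression filter requires TPM, got {mouse_expr.unit!r}")
    return mouse_expr.values.mean(axis=1)


def filter_candidates(scores: list[GeneScore], orthology: OrthologyTable,
                      mouse_expr: ExpressionMatrix,
                      tpm_threshold: float = DEFAULT_TPM_THRESHOLD
                      ) -> list[GeneScore]:
    """Keep genes with a one-to-one mouse ortholog expressed in brain.

    A gene passes when its ortholog's mean TPM across the reference samples
    is at or above ``tpm_threshold``.  Relative order is preserved.
    """
    means = mean_tpm(mouse_expr)
    kept = []
    for gs in scores:
        mg = orthology.mouse_for(gs.gene)
        if mg is None or mg not in means.index:
            continue
        if means[mg] >= tpm_threshold:
            kept.append(gs)
    return kept


def select_top_fraction(scores: list[GeneScore],
                        fraction: float = DEFAULT_TOP_FRACTION) -> list[str]:
    """First ``ceil(fraction * n)`` genes of an already-ranked score list."""
    if not (0 < fraction <= 1):
        raise ContractError(f"fraction must be in (0, 1], got {fraction}")
    if not scores:
        return []
    n_take = math.ceil(fraction * len(scores))
    return [gs.gene for gs in scores[:n_take]]


def assemble_panel(per_module_selections: dict[str, list[str]],
                   orthology: OrthologyTable,
                   housekeeping: list[str],
                   drug_targets: list[str],
                   capacity: int = DEFAULT_CAPACITY,
                   scores: dict[tuple[str, str], float] | None = None
                   ) -> tuple[PanelDefinition, list[str]]:
    """Merge per-module human selections into one mouse-gene panel.

    Human genes map to mouse genes via orthology; a gene selected by several
    modules becomes one entry annotated with the union of module ids.
    Housekeeping and drug-target entries are always included.  When demand
    exceeds ``capacity``, key entries are dropped lowest-global-score-first
    (global score = the gene's maximum score over selecting modules) and the
    truncation is reported in the returned message list.

    Returns ``(panel, report)`` where ``report`` lists truncations and
    category collisions in human-readable lines.
    """
    if not housekeeping:
        raise ContractError("housekeeping list must be nonempty")
    reserved = len(set(housekeeping)) + len(set(drug_targets) - set(housekeeping))
    if capacity < reserved:
        raise ContractError(
            f"capacity {capacity} below housekeeping+drug_target demand "
            f"{reserved}")
    report: list[str] = []
    key_entries: dict[str, set[str]] = {}
    key_scores: dict[str, float] = {}
    for mid in sorted(per_module_selections):
        for hg in per_module_selections[mid]:
            mg = orthology.mouse_for(hg)
            if mg is None:
                continue
            key_entries.setdefault(mg, set()).add(mid)
            s = scores.get((mid, hg), 0.0) if scores else 0.0
            key_scores[mg] = max(key_scores.get(mg, 0.0), s)
    hk = sorted(set(housekeeping))
    dt = [g for g in sorted(set(drug_targets)) if g not in hk]
    for g in hk:
        if g in key_entries:
            report.append(f"collision: {g} selected as key gene, kept as housekeeping")
            del key_entries[g]
    for g in dt:
        if g in key_entries:
            key_entries.pop(g)
    room = capacity - len(hk) - len(dt)
    ranked = sorted(key_entries,
                    key=lambda g: (-key_scores.get(g, 0.0), g))
    if len(ranked) > room:
        dropped = ranked[room:]
        report.append(
            f"truncated {len(dropped)} key genes (lowest global score first) "
            f"to fit capacity {capacity}")
        ranked = ranked[:room]
    entries = [PanelEntry(mouse_gene=g, category="key",
                          annotated_modules=frozenset(key_entries[g]),
                          score=key_scores.get(g, 0.0))
               for g in sorted(ranked)]
    entries += [PanelEntry(mouse_gene=g, category="drug_target") for g in dt]
    entries += [PanelEntry(mouse_gene=g, category="housekeeping") for g in hk]
    return PanelDefinition(entries=entries, capacity=capacity), report


def module_probe_coverage(panel: PanelDefinition,
                          modules: list[CoexpressionModule],
                          orthology: OrthologyTable) -> pd.DataFrame:
    """Per-module probe count and coverage fraction (count / module size)."""
    rows = []
    for m in modules:
        count = sum(1 for e in panel.entries
                    if m.module_id in e.annotated_modules)
        rows.append((m.module_id, count, count / m.size))
    return pd.DataFrame(rows, columns=["module_id", "probe_count",
                                       "coverage_fraction"])
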