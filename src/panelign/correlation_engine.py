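"""Per-module correlation of human and mouse expression changes.

The core evaluation: for a human co-expression module and a mouse contrast,
map the module's human genes to mouse genes through the one-to-one orthology
table, pair up the two log2 fold-change vectors (human case-vs-control,
mouse model-vs-B6), and compute Pearson's r with a two-sided p-value from
the t-transform with n − 2 degrees of freedom — cor.test semantics.  The
grid version repeats this for every mouse contrast × module, correlating
each module against the human contrast of its own cohort/region, and masks
significance at unadjusted p < alpha (a BH-adjusted column is also emitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .io_model import (CoexpressionModule, LogFCTable, OrthologyTable)

DEFAULT_N_MIN = 5
DEFAULT_ALPHA = 0.05

_CLUSTER_ORDER = {c: i for i, c in enumerate("ABCDE")}
_CLUSTER_ORDER["none"] = 5


@dataclass(frozen=True)
class CorrelationResult:
    module_id: str
    contrast_label: str
    r: float
    p: float
    n: int
    significant: bool
    insufficient_overlap: bool = False


def module_logfc_correlation(human: LogFCTable, mouse: LogFCTable,
                             module: CoexpressionModule,
                             orthology: OrthologyTable,
                             gene_subset: list[str] | None = None,
                             n_min: int = DEFAULT_N_MIN,
                             alpha: float = DEFAULT_ALPHA) -> CorrelationResult:
    """Pearson correlation of paired human/mouse logFCs within one module.

    ``gene_subset`` (mouse gene ids, e.g. panel genes) restricts the pairing
    when given.  With fewer than ``n_min`` overlapping genes the result is
    flagged ``insufficient_overlap`` rather than dropped.
    """
    subset = set(gene_subset) if gene_subset is not None else None
    pairs: list[tuple[float, float]] = []
    for hg in sorted(module.members):
        mg = orthology.mouse_for(hg)
        if mg is None or (subset is not None and mg not in subset):
            continue
        if hg in human.table.index and mg in mouse.table.index:
            pairs.append((human.logfc(hg), mouse.logfc(mg)))
    label = f"{mouse.contrast_label}|{human.contrast_label}"
    n = len(pairs)
    if n < n_min:
        return CorrelationResult(module_id=module.module_id,
                                 contrast_label=label, r=math.nan,
                                 p=math.nan, n=n, significant=False,
                                 insufficient_overlap=True)
    h = np.array([p[0] for p in pairs])
    m = np.array([p[1] for p in pairs])
    if (h == h[0]).all() or (m == m[0]).all():
        return CorrelationResult(module_id=module.module_id,
                                 contrast_label=label, r=math.nan,
                                 p=math.nan, n=n, significant=False,
                                 insufficient_overlap=True)
    r, p = stats.pearsonr(h, m)
    return CorrelationResult(module_id=module.module_id, contrast_label=label,
                             r=float(r), p=float(p), n=n,
                             significant=bool(p < alpha))


def correlation_grid(mouse_contrasts: list[LogFCTable],
                     human_contrasts: dict[str, LogFCTable],
                     modules: list[CoexpressionModule],
                     orthology: OrthologyTable,
                     alpha: float = DEFAULT_ALPHA,
                     gene_subset: list[str] | None = None,
                     n_min: int = DEFAULT_N_MIN) -> pd.DataFrame:
    """The mouse-contrast × module correlation grid.

    ``human_contrasts`` is keyed by brain region; each module is correlated
    against the human contrast of its own region.  Rows are ordered by
    mouse contrast, then consensus cluster A–E, then module id.  Columns:
    contrast, module, cluster, r, p, adj_p, n, significant.
    """
    for m in modules:
        if m.brain_region not in human_contrasts:
            raise ContractError(
                f"module {m.module_id!r}: no human contrast for region "
                f"{m.brain_region!r}")
    ordered = sorted(modules, key=lambda m: (
        _CLUSTER_ORDER.get(m.consensus_cluster, 5), m.module_id))
    rows = []
    for mc in mouse_contrasts:
        for mod in ordered:
            hc = human_contrasts[mod.brain_region]
            res = module_logfc_correlation(hc, mc, mod, orthology,
                                           gene_subset=gene_subset,
                                           n_min=n_min, alpha=alpha)
            rows.append({"contrast": mc.contrast_label,
                         "module": mod.module_id,
                         "cluster": mod.consensus_cluster,
                         "r": res.r, "p": res.p, "n": res.n,
                         "significant": res.significant,
                         "insufficient_overlap": res.insufficient_overlap})
    grid = pd.DataFrame(rows)
    ok = grid["p"].notna()
    adj = np.full(len(grid), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(grid.loc[ok, "p"],
                                           method="fdr_bh")[1]
    grid["adj_p"] = adj
    return grid[["contrast", "module", "cluster", "r", "p", "adj_p", "n",
                 "significant", "insufficient_overlap"]]
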