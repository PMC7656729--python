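"""Cross-species module conservation: sequence divergence vs brain expression.

Two per-module summaries are computed and correlated across modules:

* ``median_dnds`` — the median dN/dS over module genes with a defined
  one-to-one ortholog ratio (dS > 0); lower values mean stronger purifying
  selection on the module's coding sequences.
* ``fraction_expressed`` — the fraction of module genes whose mouse ortholog
  is detectably expressed (mean TPM at or above a threshold, default 1) in
  reference mouse brain samples.

On real brain data these two are strongly inversely related: recently
diverged (e.g. immune) modules are also the least expressed in mouse brain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, InsufficientDataError
from .io_model import CoexpressionModule, ExpressionMatrix, OrthologyTable
from .prioritization import DEFAULT_TPM_THRESHOLD, mean_tpm


@dataclass(frozen=True)
class ModuleConservation:
    module_id: str
    median_dnds: float          # NaN when no ortholog has a defined ratio
    fraction_expressed: float   # denominator: module size
    fraction_expressed_orthologs: float  # denominator: ortholog count
    n_orthologs: int


def module_median_dnds(module: CoexpressionModule,
                       orthology: OrthologyTable) -> float:
    """Median dN/dS over module members with a defined ortholog ratio.

    Returns NaN when no module gene has a one-to-one ortholog with dS > 0.
    """
    vals = [orthology.dnds_for(g) for g in module.members]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return math.nan
    return float(np.median(vals))


def module_fraction_expressed(module: CoexpressionModule,
                              orthology: OrthologyTable,
                              mouse_expr: ExpressionMatrix,
                              tpm_threshold: float = DEFAULT_TPM_THRESHOLD
                              ) -> float:
    """Fraction of module genes with an expressed one-to-one mouse ortholog.

    Genes without an ortholog count in the denominator but can never count
    as expressed.
    """
    if not module.members:
        raise ContractError(f"module {module.module_id!r} is empty")
    means = mean_tpm(mouse_expr)
    n_expr = 0
    for g in module.members:
        mg = orthology.mouse_for(g)
        if mg is not None and mg in means.index and means[mg] >= tpm_threshold:
            n_expr += 1
    return n_expr / module.size


def conservation_profile(modules: list[CoexpressionModule],
                         orthology: OrthologyTable,
                         mouse_expr: ExpressionMatrix,
                         tpm_threshold: float = DEFAULT_TPM_THRESHOLD
                         ) -> tuple[pd.DataFrame, float, float]:
    """Per-module conservation table plus the cross-module Pearson r and p.

    The correlation is between ``median_dnds`` and ``fraction_expressed``
    over modules where the median is defined; p is two-sided from the
    t-transform with n − 2 degrees of freedom.
    """
    means = mean_tpm(mouse_expr)
    rows = []
    for m in modules:
        med = module_median_dnds(m, orthology)
        n_orth = sum(1 for g in m.members if orthology.mouse_for(g) is not None)
        n_expr = 0
        for g in m.members:
            mg = orthology.mouse_for(g)
            if mg is not None and mg in means.index and means[mg] >= tpm_threshold:
                n_expr += 1
        rows.append(ModuleConservation(
            module_id=m.module_id,
            median_dnds=med,
            fraction_expressed=n_expr / m.size,
            fraction_expressed_orthologs=(n_expr / n_orth) if n_orth else math.nan,
            n_orthologs=n_orth))
    table = pd.DataFrame([r.__dict__ for r in rows])
    usable = table.dropna(subset=["median_dnds"])
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} modules with defined median dN/dS (< 3)")
    r, p = stats.pearsonr(usable["median_dnds"], usable["fraction_expressed"])
    return table, float(r), float(p)
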