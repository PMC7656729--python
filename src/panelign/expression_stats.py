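"""Normalization and moderated differential expression.

Counts from a hybridization panel are normalized per lane by the geometric
mean of designated housekeeping genes in that lane, then log2-transformed
with a pseudocount.  RNA-Seq style raw counts can instead go through log-CPM.
Differential expression between two explicit sample groups uses a moderated
t-statistic: gene-wise variances are shrunk toward a common prior fitted by
method of moments (a scaled inverse-chi-square prior, equivalently
``s_g^2 ~ s0^2 * F(d_res, d0)`` under the null), which stabilizes inference
at the small group sizes typical of mouse cohorts.  P-values are two-sided
from the t distribution with ``d_res + d0`` degrees of freedom and are
BH-adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, DataError, InsufficientDataError
from .io_model import ExpressionMatrix, LogFCTable


@dataclass(frozen=True)
class DEConfig:
    pseudocount: float = 1.0
    shrinkage: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ContractError(f"alpha must be in (0,1), got {self.alpha}")


def housekeeping_normalize(counts: ExpressionMatrix,
                           housekeeping: list[str]) -> ExpressionMatrix:
    """Divide each lane's counts by that lane's housekeeping geometric mean."""
    if counts.unit != "raw_count":
        raise ContractError(
            f"housekeeping normalization expects raw counts, got {counts.unit!r}")
    missing = [g for g in housekeeping if g not in counts.values.index]
    if missing:
        raise ContractError(f"housekeeping gene(s) absent: {missing}")
    hk = counts.values.loc[housekeeping]
    for sample in counts.samples:
        col = hk[sample]
        if (col <= 0).any():
            gene = col.index[col <= 0][0]
            raise DataError(
                f"housekeeping gene {gene!r} has non-positive count in lane "
                f"{sample!r}")
    geo = np.exp(np.log(hk).mean(axis=0))
    normalized = counts.values / geo
    return counts.with_values(normalized, "normalized")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0
                  ) -> ExpressionMatrix:
    """value -> log2(value + pseudocount)."""
    if m.unit not in ("normalized", "tpm"):
        raise ContractError(f"log transform expects normalized/tpm, got {m.unit!r}")
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ContractError("negative value in matrix to log-transform")
    if pseudocount == 0 and (arr == 0).any():
        raise ContractError("zero value with zero pseudocount would give -inf")
    return m.with_values(np.log2(m.values + pseudocount), "log_normalized")


def log_cpm(counts: ExpressionMatrix, pseudocount: float = 0.5
            ) -> ExpressionMatrix:
    """log2 counts-per-million for the RNA-Seq path."""
    if counts.unit != "raw_count":
        raise ContractError(f"log-CPM expects raw counts, got {counts.unit!r}")
    lib = counts.values.sum(axis=0)
    cpm = (counts.values + pseudocount) / (lib + 1.0) * 1e6
    return counts.with_values(np.log2(cpm), "log_normalized")


def _fit_variance_prior(s2: np.ndarray, d_res: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Under the hierarchical model s_g^2 ~ s0^2 F(d_res, d0).  Matching the
    first two moments of the observed gene variances gives d0 and s0^2;
    when the observed spread is no larger than sampling noise alone, the
    prior df is effectively infinite and we clamp it.
    """
    pos = s2[s2 > 0]
    if pos.size < 2:
        return 1e6, float(pos.mean()) if pos.size else 1.0
    m = pos.mean()
    cv2 = pos.var(ddof=1) / m**2
    # cv2 = 2 (d_res + d0 - 2) / (d_res (d0 - 4))
    denom = cv2 * d_res - 2
    if denom <= 0:
        d0 = 1e6
    else:
        d0 = (4 * cv2 * d_res + 2 * d_res - 4) / denom
        d0 = max(d0, 1e-2)
    if not np.isfinite(d0) or d0 > 1e6:
        d0 = 1e6
    if d0 > 2:
        s0 = m * (d0 - 2) / d0
    else:
        s0 = m
    return float(d0), float(s0)


def differential_expression(m: ExpressionMatrix, group_a: list[str],
                            group_b: list[str],
                            config: DEConfig = DEConfig(),
                            contrast_label: str = "a_vs_b") -> LogFCTable:
    """Per-gene moderated-t differential expression, group_a minus group_b."""
    if m.unit != "log_normalized":
        raise ContractError(
            f"differential expression expects log-normalized data, got "
            f"{m.unit!r}")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ContractError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per group, got {len(group_a)} and "
            f"{len(group_b)}")
    for s in list(group_a) + list(group_b):
        if s not in m.values.columns:
            raise ContractError(f"sample {s!r} not in matrix")
    A = m.values[list(group_a)].to_numpy(dtype=float)
    B = m.values[list(group_b)].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    logfc = A.mean(axis=1) - B.mean(axis=1)
    d_res = na + nb - 2
    pooled = (A.var(axis=1, ddof=1) * (na - 1)
              + B.var(axis=1, ddof=1) * (nb - 1)) / d_res
    if config.shrinkage:
        d0, s0 = _fit_variance_prior(pooled, d_res)
        s2_post = (d0 * s0 + d_res * pooled) / (d0 + d_res)
        df_total = min(d0 + d_res, 1e6)
    else:
        s2_post = pooled.copy()
        # genes with zero variance are untestable without a prior
        s2_post[s2_post == 0] = np.nan
        df_total = d_res
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(p), p, 1.0)
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"logfc": logfc, "p": p, "adj_p": adj},
                         index=m.values.index)
    return LogFCTable(contrast_label, table)
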