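"""Seeded generators for every input the pipeline consumes.

Each generator plants a known structure so downstream stages have a ground
truth to recover:

* modules — disjoint human gene sets assigned round-robin to consensus
  clusters A–E, with cohort/brain-region provenance.
* human cohort — one latent factor per module; each gene is
  ``loading * factor + noise`` and cases shift the factor mean by the
  module's effect size, so the true logFC of a gene is ``loading * effect``.
  A configurable "strong" subset of each module gets high loadings — these
  are the genes a loading-based ranking should recover.
* orthology + mouse reference brain expression — one-to-one pairs whose
  per-module median dN/dS and expressed fraction follow a configured
  (negative) linear link, emulating the divergence-vs-expression relation
  seen between immune and neuronal brain modules.
* mouse model counts — negative-binomial counts with log2 link whose true
  model-vs-control logFCs are drawn jointly with the human logFCs at a
  planted per-module correlation (concordance), plus near-constant
  housekeeping genes.
* transcriptome — random-GC transcripts with 1–4 isoforms per gene and
  optional planted features (shared off-target motif, poly-A island).

All generators are deterministic under ``config.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_model import (ANNOTATION_KEYS, CoexpressionModule, ExpressionMatrix,
                       LogFCTable, OrthologyTable, write_expression_matrix,
                       write_logfc_table, write_module_table,
                       write_orthology_table)
from .probe_design import TranscriptRecord

COHORTS = ("ROSMAP", "Mayo", "MSBB")
REGIONS = ("DLPFC", "CBE", "TCX", "FP", "IFG", "PHG", "STG")
CLUSTERS = ("A", "B", "C", "D", "E")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the package's study conditions."""

    seed: int = 0
    n_modules: int = 30
    module_sizes: list[int] = field(default_factory=list)  # cycle below if empty
    # human cohort
    n_case: int = 50
    n_control: int = 50
    module_effect_sizes: list[float] = field(default_factory=list)
    noise_sd: float = 1.0
    loading_high: float = 0.9
    loading_low: float = 0.3
    strong_fraction: float = 0.25
    # mouse models
    module_concordance: list[float] = field(default_factory=list)
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 7.0
    n_mouse_per_group: int = 10
    mouse_logfc_sd: float = 0.5
    n_housekeeping: int = 10
    # orthology / conservation link
    ortholog_fraction: float = 0.9
    ds_zero_fraction: float = 0.05
    dnds_base: float = 0.05
    dnds_spread: float = 0.4
    expressed_link_intercept: float = 1.0
    expressed_link_slope: float = -2.0
    link_noise_sd: float = 0.02
    # transcriptome
    transcript_length_range: tuple[int, int] = (600, 1200)
    gc_target: float = 0.5

    def sizes(self) -> list[int]:
        if self.module_sizes:
            if any(s <= 0 for s in self.module_sizes):
                raise ContractError("module sizes must be positive")
            return list(self.module_sizes)
        cycle = [60, 80, 100, 120, 150]
        return [cycle[i % len(cycle)] for i in range(self.n_modules)]

    def effects(self) -> list[float]:
        if self.module_effect_sizes:
            return list(self.module_effect_sizes)
        cycle = [1.0, -0.8, 0.6, -0.6, 0.8]
        return [cycle[i % len(cycle)] for i in range(self.n_modules)]

    def concordances(self) -> list[float]:
        if self.module_concordance:
            bad = [c for c in self.module_concordance if not -1 <= c <= 1]
            if bad:
                raise ContractError(f"concordance outside [-1,1]: {bad}")
            return list(self.module_concordance)
        cycle = [0.6, 0.3, 0.0, -0.3, -0.6]
        return [cycle[i % len(cycle)] for i in range(self.n_modules)]


def _human_gene(i: int) -> str:
    return f"HG{i:05d}"


def _mouse_gene(i: int) -> str:
    return f"Mg{i:05d}"


def simulate_modules(config: SimulationConfig
                     ) -> tuple[list[CoexpressionModule], dict[str, str]]:
    """Disjoint modules over a synthetic human namespace, clusters round-robin."""
    sizes = config.sizes()
    modules = []
    clusters: dict[str, str] = {}
    gene_i = 0
    for m in range(config.n_modules):
        members = frozenset(_human_gene(gene_i + k) for k in range(sizes[m]))
        gene_i += sizes[m]
        cluster = CLUSTERS[m % len(CLUSTERS)]
        mod = CoexpressionModule(
            module_id=f"HM{m + 1:02d}",
            cohort=COHORTS[m % len(COHORTS)],
            brain_region=REGIONS[m % len(REGIONS)],
            consensus_cluster=cluster,
            members=members)
        modules.append(mod)
        clusters[mod.module_id] = cluster
    return modules, clusters


def module_loadings(modules: list[CoexpressionModule],
                    config: SimulationConfig) -> dict[str, float]:
    """Per-gene factor loading; the lexicographically first ``strong_fraction``
    of each module gets ``loading_high``, the rest ``loading_low``."""
    loadings: dict[str, float] = {}
    for mod in modules:
        members = sorted(mod.members)
        n_strong = int(np.ceil(config.strong_fraction * len(members)))
        for k, g in enumerate(members):
            loadings[g] = (config.loading_high if k < n_strong
                           else config.loading_low)
    return loadings


def strong_genes(modules: list[CoexpressionModule],
                 config: SimulationConfig) -> dict[str, list[str]]:
    """The planted high-loading gene subset per module."""
    out = {}
    for mod in modules:
        members = sorted(mod.members)
        n_strong = int(np.ceil(config.strong_fraction * len(members)))
        out[mod.module_id] = members[:n_strong]
    return out


def simulate_human_cohort(modules: list[CoexpressionModule],
                          config: SimulationConfig
                          ) -> tuple[ExpressionMatrix, LogFCTable]:
    """Latent-factor case/control cohort and its true logFC table.

    Gene value = loading * module factor + N(0, noise_sd); cases shift each
    module's factor mean by the module effect, so true logFC =
    loading * effect (log2 scale).
    """
    rng = np.random.default_rng(config.seed)
    effects = config.effects()
    loadings = module_loadings(modules, config)
    n = config.n_case + config.n_control
    samples = [f"case{i:03d}" for i in range(config.n_case)] + \
              [f"ctrl{i:03d}" for i in range(config.n_control)]
    case_mask = np.array([1.0] * config.n_case + [0.0] * config.n_control)
    genes: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, float] = {}
    for mi, mod in enumerate(modules):
        factor = rng.normal(size=n) + case_mask * effects[mi]
        for g in sorted(mod.members):
            lam = loadings[g]
            rows.append(lam * factor + rng.normal(scale=config.noise_sd, size=n))
            genes.append(g)
            truth[g] = lam * effects[mi]
    values = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    ann = pd.DataFrame({
        "group": ["case"] * config.n_case + ["control"] * config.n_control,
        "model": "human", "age_months": 0, "sex": "NA",
        "lane": [f"L{i % 8 + 1}" for i in range(n)]}, index=samples)
    ann.index.name = "sample"
    expr = ExpressionMatrix(values, "log_normalized", ann)
    ttab = pd.DataFrame({"logfc": [truth[g] for g in genes],
                         "p": 1.0, "adj_p": 1.0}, index=genes)
    return expr, LogFCTable("human_case_vs_control_true", ttab)


def simulate_orthology(modules: list[CoexpressionModule],
                       config: SimulationConfig
                       ) -> tuple[OrthologyTable, ExpressionMatrix]:
    """One-to-one orthology with a planted divergence-vs-expression link.

    Each module gets a dN/dS center in ``[dnds_base, dnds_base+dnds_spread]``;
    the fraction of its genes expressed in the reference mouse brain follows
    ``intercept + slope * center`` plus noise.  Returns the orthology table
    and a small reference mouse brain TPM matrix realizing the expressed
    fractions (expressed orthologs well above the TPM=1 cutoff, the rest
    well below).
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    tpm_means: dict[str, float] = {}
    mouse_i = 0
    for mod in modules:
        members = sorted(mod.members)
        center = config.dnds_base + config.dnds_spread * rng.random()
        frac = (config.expressed_link_intercept
                + config.expressed_link_slope * center
                + rng.normal(scale=config.link_noise_sd))
        frac = float(np.clip(frac, 0.02, 0.98))
        has_orth = rng.random(len(members)) < config.ortholog_fraction
        orth_idx = [k for k, h in enumerate(has_orth) if h]
        n_expr = min(int(round(frac * len(members))), len(orth_idx))
        expressed = set(orth_idx[:n_expr])
        for k in orth_idx:
            hg = members[k]
            mg = _mouse_gene(mouse_i)
            mouse_i += 1
            dnds = max(rng.normal(loc=center, scale=0.15 * center + 1e-3), 1e-4)
            if rng.random() < config.ds_zero_fraction:
                ds, dn = 0.0, rng.uniform(0.0, 0.1)
            else:
                ds = rng.uniform(0.5, 1.5)
                dn = dnds * ds
            rows.append((hg, mg, dn, ds))
            tpm_means[mg] = (rng.uniform(5.0, 50.0) if k in expressed
                             else rng.uniform(0.0, 0.5))
    orth = OrthologyTable(pd.DataFrame(
        rows, columns=["human_gene", "mouse_gene", "dn", "ds"]))
    samples = [f"b6ref{i}" for i in range(4)]
    mg_sorted = sorted(tpm_means)
    vals = pd.DataFrame(
        np.tile([[tpm_means[g]] for g in mg_sorted], (1, len(samples))),
        index=mg_sorted, columns=samples)
    ann = pd.DataFrame({"group": "reference", "model": "B6",
                        "age_months": 6, "sex": "M",
                        "lane": [f"L{i + 1}" for i in range(len(samples))]},
                       index=samples)
    ann.index.name = "sample"
    return orth, ExpressionMatrix(vals, "tpm", ann)


def housekeeping_genes(config: SimulationConfig) -> list[str]:
    return [f"Hk{i + 1:02d}" for i in range(config.n_housekeeping)]


def simulate_mouse_models(modules: list[CoexpressionModule],
                          orthology: OrthologyTable,
                          human_truth: LogFCTable,
                          config: SimulationConfig,
                          model_name: str = "modelA"
                          ) -> tuple[ExpressionMatrix, LogFCTable]:
    """Negative-binomial mouse counts with planted human concordance.

    Within each module the true mouse logFCs are
    ``rho * z_h + sqrt(1 - rho^2) * eps`` (z_h = standardized human true
    logFCs, eps standard normal), rescaled to ``mouse_logfc_sd`` — a
    bivariate-normal draw whose expected per-module Pearson correlation with
    the human logFCs is the planted concordance.  Housekeeping genes have a
    group effect of exactly zero.
    """
    rng = np.random.default_rng(config.seed + 2)
    conc = config.concordances()
    truth: dict[str, float] = {}
    for mi, mod in enumerate(modules):
        members = sorted(mod.members)
        h = np.array([human_truth.logfc(g) for g in members])
        sd = h.std()
        z = (h - h.mean()) / sd if sd > 0 else np.zeros(len(h))
        rho = conc[mi]
        eps = rng.normal(size=len(h))
        zm = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps
        for g, v in zip(members, zm):
            mg = orthology.mouse_for(g)
            if mg is not None:
                truth[mg] = float(v * config.mouse_logfc_sd)
    hk = housekeeping_genes(config)
    genes = sorted(truth) + hk
    n = config.n_mouse_per_group
    samples = [f"{model_name}_{i:02d}" for i in range(n)] + \
              [f"B6_{i:02d}" for i in range(n)]
    is_model = np.array([1.0] * n + [0.0] * n)
    disp_n = 1.0 / config.nb_dispersion
    mat = np.empty((len(genes), 2 * n))
    for gi, g in enumerate(genes):
        lfc = truth.get(g, 0.0)  # housekeeping: exactly 0
        mean = 2.0 ** (config.baseline_log2_mean + is_model * lfc)
        p = disp_n / (disp_n + mean)
        mat[gi] = rng.negative_binomial(disp_n, p)
    values = pd.DataFrame(mat, index=genes, columns=samples)
    ann = pd.DataFrame({
        "group": [model_name] * n + ["B6"] * n,
        "model": [model_name] * n + ["B6"] * n,
        "age_months": 6,
        "sex": ["M", "F"] * n,
        "lane": [f"L{i % 12 + 1}" for i in range(2 * n)]}, index=samples)
    ann.index.name = "sample"
    counts = ExpressionMatrix(values, "raw_count", ann)
    ttab = pd.DataFrame({"logfc": [truth.get(g, 0.0) for g in genes],
                         "p": 1.0, "adj_p": 1.0}, index=genes)
    return counts, LogFCTable(f"{model_name}_vs_B6_true", ttab)


_BASES = np.array(list("GCAT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_transcriptome(genes: list[str], config: SimulationConfig,
                           off_target_pair: tuple[str, str] | None = None,
                           polya_genes: list[str] | None = None,
                           max_isoforms: int = 4
                           ) -> list[TranscriptRecord]:
    """Random transcripts, 1–4 isoforms per gene, optional planted features.

    ``off_target_pair`` embeds one shared 40-nt motif verbatim in both named
    genes; ``polya_genes`` get a 30-nt poly-A island in every window of the
    first isoform's middle.  Isoforms beyond the first are subsequences of
    the first (sharing most of their sequence), so probes from the shared
    region cover all isoforms.
    """
    rng = np.random.default_rng(config.seed + 3)
    lo, hi = config.transcript_length_range
    motif = _random_seq(rng, 40, config.gc_target) if off_target_pair else ""
    records = []
    for gene in genes:
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length, config.gc_target)
        if off_target_pair and gene in off_target_pair:
            pos = length // 2
            seq = seq[:pos] + motif + seq[pos + 40:]
        if polya_genes and gene in polya_genes:
            pos = length // 3
            seq = seq[:pos] + "A" * 30 + seq[pos + 30:]
        n_iso = int(rng.integers(1, max_isoforms + 1))
        records.append(TranscriptRecord(
            transcript_id=f"{gene}.1", gene=gene, sequence=seq))
        for k in range(2, n_iso + 1):
            trim5 = int(rng.integers(0, min(80, length // 8)))
            trim3 = int(rng.integers(0, min(80, length // 8)))
            records.append(TranscriptRecord(
                transcript_id=f"{gene}.{k}", gene=gene,
                sequence=seq[trim5:length - trim3]))
    return records


def write_transcripts(records: list[TranscriptRecord], path: str | Path) -> None:
    lines = []
    for t in records:
        lines.append(f">{t.transcript_id} gene={t.gene}")
        for i in range(0, len(t.sequence), 70):
            lines.append(t.sequence[i:i + 70])
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Run every generator and write the full input bundle to ``out_dir``.

    Returns the truth summary (also written as truth.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    modules, clusters = simulate_modules(config)
    write_module_table(modules, out / "modules.tsv")
    human_expr, human_truth = simulate_human_cohort(modules, config)
    write_expression_matrix(human_expr, out / "human_expr.tsv",
                            out / "human_annotations.tsv")
    write_logfc_table(human_truth, out / "human_logfc_true.tsv")
    orth, mouse_ref = simulate_orthology(modules, config)
    write_orthology_table(orth, out / "orthology.tsv")
    write_expression_matrix(mouse_ref, out / "mouse_ref_tpm.tsv",
                            out / "mouse_ref_annotations.tsv")
    counts, mouse_truth = simulate_mouse_models(modules, orth, human_truth,
                                                config)
    write_expression_matrix(counts, out / "mouse_counts.tsv",
                            out / "mouse_annotations.tsv")
    write_logfc_table(mouse_truth, out / "mouse_logfc_true.tsv")
    hk = housekeeping_genes(config)
    (out / "housekeeping.txt").write_text("\n".join(hk) + "\n")
    truth = {
        "seed": config.seed,
        "n_modules": len(modules),
        "clusters": clusters,
        "module_effect_sizes": config.effects()[:len(modules)],
        "module_concordance": config.concordances()[:len(modules)],
        "strong_genes": strong_genes(modules, config),
        "housekeeping": hk,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
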