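# Methods

This note documents the models, conventions and numerical choices behind
`panelign`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Gene prioritization within modules

A co-expression module is treated as a fixed human gene set with
cohort/brain-region provenance and a consensus-cluster label (A–E). For a
module with expression submatrix X (samples × genes), genes are centered
and scaled to unit variance and the principal components of the
standardized submatrix are taken (samples as observations). Constant genes
are dropped from the decomposition and score 0. With sample-score vectors
PC₁..PC₅ and variance fractions ve₁..ve₅ — fractions of the *total*
variance of the standardized submatrix, i.e. eigenvalues divided by the
number of genes, matching how "percentage of variation explained" is
ordinarily reported — the score of gene *g* is

    s_g = | Σ_{k=1..5} r_gk · ve_k |

with r_gk the Pearson correlation between the gene's expression vector and
PC_k. The absolute value is taken after summation (a gene consistently
anti-correlated with the leading components ranks as highly as a correlated
one); the alternative aggregation Σ|r·ve| is available as the
`sum-of-abs` variant, since either reading is defensible and the two can
disagree for genes with mixed-sign loadings. The default is `abs-of-sum`.

Sign convention: each component's score vector is oriented so that its
largest-magnitude gene loading is positive. This makes r_gk reproducible
across linear-algebra backends; the score itself is sign-invariant.

Ranked genes are filtered to those with a one-to-one mouse ortholog whose
mean TPM across reference brain samples is ≥ 1 — the expressed/absent
cutoff used throughout — and the top 5% of the *filtered* list is selected
per module (rank → filter → select). The ceiling rule `ceil(0.05·n)`
guarantees a nonempty selection for small modules. Filtering before
selection (rather than after) was chosen so that every selected gene is
actually measurable in mouse; the alternative order would let unmeasurable
genes consume selection slots.

Panel assembly maps selections to mouse gene space, merges duplicates (a
gene chosen by several modules yields one entry annotated with the union of
module ids), always includes the housekeeping and drug-target lists, and —
when demand exceeds the 770-probe capacity — drops key entries
lowest-global-score-first, where a gene's global score is its maximum score
over the modules that selected it. A housekeeping gene that is also
selected as a key gene stays housekeeping (reference genes must not carry
disease annotations) and the collision is reported.

## Conservation

Module conservation is summarized by (i) the median dN/dS over module genes
with a defined ortholog ratio — pairs with dS = 0 have an undefined ratio
and are excluded — and (ii) the fraction of module genes whose ortholog is
expressed (mean TPM ≥ threshold) in reference mouse brain. The fraction
uses module size as denominator, so genes without orthologs count against
expression; a companion column with ortholog count as denominator is also
emitted since the choice is a genuine interpretation point. The
cross-module association is Pearson's r with a two-sided p from the
t-transform; at least 3 modules with defined medians are required. Even
medians use the mean of the central pair.

## Probe design

Transcripts are scanned in 100-nt windows (stride 1 by default,
configurable). Windows are hard-filtered — rather than penalty-scored, for
auditability — on: any non-canonical base; a homopolymer run ≥ 6; a direct
repeat (some ≥ 8-nt substring occurring twice disjointly); an inverted
repeat (some ≥ 8-nt substring whose reverse complement also occurs). A
surviving window is split at its midpoint and each half is tuned from its
5′ end to the probe length in 35–50 nt whose predicted Tm is closest to the
78 °C target (ties break shorter). The pair is therefore always adjacent
and non-overlapping within one window. The 78 °C target and the filter
constants are package conventions, exposed in `ProbeDesignConfig`.

Melting temperatures come from a unified nearest-neighbor model
(SantaLucia-1998-style ΔH/ΔS stack table shipped as data) with the
entropic salt correction 0.368·(N−1)·ln[Na⁺] and the two-state formula at
50 mM Na⁺ and 0.25 µM total strand concentration. ΔG37 uses the same
salt-corrected entropy. The test suite checks the implementation against an
independently published-parameter oracle to 0.1 °C.

Cross-hybridization: exact 12-mer seeds shared with transcripts of other
genes nominate diagonals; on each diagonal the best contiguous segment
under match +1 / mismatch −2 scoring is found, and the score is that
segment's match count divided by probe length (0 with no seeds, 1.0 for a
verbatim off-target copy). This seeded ungapped scheme is this package's
screening convention; tests verify it against an exhaustive alignment
oracle on fixtures. Splice-isoform coverage is the fraction of the gene's
isoforms containing the probe subsequence exactly; for a pair, both probes
must be present.

Candidates are ranked by the tuple (isoform coverage desc, cross-hyb asc,
max pair |Tm − target| asc, window start asc); ties cannot survive the
final position key, so design is deterministic. Coordinates are 0-based
half-open internally and 1-based inclusive in reports.

## Panel QC

For every unordered pair of panel probes, the longest perfectly
complementary stretch over all duplex registers (equivalently, the longest
common aligned run between one probe and the reverse complement of the
other) is evaluated with the nearest-neighbor model; stretches shorter than
8 nt are ignored (ΔG sentinel 0). A pair conflicts when ΔG37 ≤ −18
kcal/mol or duplex Tm ≥ 40 °C — thresholds chosen so that only long
complementary islands trip them, and configurable. Internal mismatches and
loops are deliberately not modeled; a partition-function hybridization
model is out of scope. Resolution walks conflicts in panel-entry order and
replaces the worse-ranked member with its gene's next-ranked alternative,
re-screening each round; it errors distinctly on exhausted alternatives
versus exhausted rounds.

## Normalization and differential expression

Hybridization-panel counts are normalized per lane by the geometric mean of
the designated housekeeping genes in that lane (after which each lane's
housekeeping geometric mean is exactly 1), then log2-transformed with
pseudocount 1. RNA-Seq counts instead go through log2-CPM. Differential
expression between two explicit sample groups uses a moderated t-statistic:
pooled gene variances s²_g with d_res degrees of freedom are shrunk toward
a prior fitted by method of moments under s²_g ~ s₀²·F(d_res, d₀)
(equivalently a scaled inverse-chi-square prior on σ²_g), giving posterior
variances (d₀s₀² + d_res s²_g)/(d₀ + d_res) and t with d_res + d₀ degrees
of freedom. When the observed variance spread is no larger than sampling
noise, d₀ is effectively infinite and is clamped at 10⁶; zero-variance
genes inherit the prior. P-values are two-sided and BH-adjusted across
genes. No precision weights or covariate modeling: contrasts are explicit
sample sets.

## Module logFC correlation

For a module and a mouse contrast, human genes are mapped to mouse genes
via the one-to-one orthology table (optionally restricted to a gene subset
such as the panel), the paired log2 fold-change vectors are correlated
(Pearson), and p comes from the t-transform with n−2 df — cor.test
semantics. At least 5 overlapping genes are required (3 is the algebraic
minimum; 5 guards degenerate p-values); a smaller overlap is flagged
`insufficient_overlap` rather than dropped, so grid shape is always
|contrasts| × |modules|. The grid orders modules by consensus cluster A–E
then id, masks significance at unadjusted p < 0.05 (mirroring how such
grids are usually displayed), and emits a BH-adjusted column alongside.
Orientation: human logFC is case minus control; mouse is model minus
age-matched control.

## Enrichment

Over-representation p-values are exact upper-tail hypergeometric
probabilities P(X ≥ overlap); sets are ranked by Bonferroni-corrected p
(the convention for pathway annotation), with BH also reported.
Consensus-cluster annotation emits terms in rank order, suppressing any set
with Jaccard ≥ 0.5 against an already-emitted set — the quantified form of
"non-overlapping" — and warns when nothing is significant at Bonferroni
0.05.

GSEA uses the classic weighted running sum (weight 1 by default): hits add
|logFC|^w normalized by total hit weight, misses subtract 1/(N − set
size), ES is the extremum. The null is gene-label permutation (not
phenotype permutation — deterministic and well-defined at the small sample
counts this package targets) at a fixed seed; NES divides ES by the mean
|null ES| of the same sign; p uses +1 smoothing, so p ≥ 1/(n_perm+1).
The ES agrees bit-for-bit with an independent implementation on fixtures.

## Synthetic data

The generators produce every pipeline input with planted truth, emulating
the statistical structure of a multi-cohort brain study at desk scale:

* **Modules:** 30 disjoint modules by default, sizes cycling
  60/80/100/120/150, assigned round-robin to clusters A–E and to three
  cohorts/seven brain regions.
* **Human cohort:** one latent factor per module; gene value =
  loading · factor + N(0,1) noise; cases shift the factor mean by the
  module effect (log2 units, defaults cycling ±0.6–1.0), so true
  logFC = loading·effect. A configurable leading subset of each module
  (default 25%) carries high loadings (0.9 vs 0.3) — the genes a
  loading-based ranking should find. Default 50 cases + 50 controls.
* **Orthology + reference brain:** ~90% of genes get a one-to-one mouse
  ortholog; 5% of pairs have dS = 0 (undefined ratio). Each module draws a
  dN/dS center in [0.05, 0.45] and its expressed fraction follows
  1 − 2·center plus N(0, 0.02) noise, planting a strong negative
  divergence-expression link; expressed orthologs get mean TPM in [5, 50],
  the rest in [0, 0.5], safely either side of the TPM = 1 cutoff.
* **Mouse models:** true mouse logFCs are ρ·z_h + √(1−ρ²)·ε per module
  (z_h standardized human truth), scaled to sd 0.5 — a bivariate-normal
  construction whose expected per-module correlation with human truth is
  the planted concordance ρ (defaults cycling +0.6…−0.6). Counts are
  negative binomial with log2 link (baseline mean 2⁷, dispersion 0.1),
  10 animals per group; 10 housekeeping genes have group effect exactly 0.
* **Transcriptome:** random sequences at a target GC of 0.5, lengths
  600–1200 nt, 1–4 isoforms per gene (shorter isoforms are subsequences of
  the first), with optional planted features: a 40-nt motif shared by two
  genes (off-target fixture) or a 30-nt poly-A island (filter fixture).

Everything is byte-deterministic under the seed. What the generator does
*not* emulate: real effect-size distributions, inter-module correlation
(off by default; a knob exists), batch structure, and single-cell
heterogeneity — so green tests demonstrate correctness of the algorithms
under the stated model, not performance on real cohort data. In
particular, the human truth logFC within a module takes only two values
(strong/weak loading × effect), which is convenient for recovery tests but
unlike real data.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale as a deliberate
design point: 30 modules of 60–150 genes, 20-seed replicate loops for the
stochastic recovery checks, 1000-gene nulls for DE calibration, 100–1000
permutations for GSEA, and probe design/QC on ~10-gene transcriptomes.
Stage seeds are derived from a single master seed via `SeedSequence` so
replicate loops are reproducible and independent. The correlation-grid
null check is itself a stochastic criterion (a correctly calibrated null
module is significant in ~5% of seeds), so its 18-of-20 bound holds with
high but not certain probability for any given master seed.

## Known limitations

* The cross-hybridization score is a seeded ungapped-identity screen, not a
  full local aligner; gapped off-target matches are invisible to it.
* The duplex screen scores only perfect complementary stretches; bulged or
  mismatched duplexes are not modeled.
* The moderated-t implementation fits the variance prior by moments, which
  is simpler but less efficient than likelihood-based fits at very small
  gene counts.
* The GSEA null permutes gene labels, which ignores inter-gene correlation;
  its p-values are calibrated under the generator's independence model
  only.
* RCC ingestion supports the sectioned-text lane format only.
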