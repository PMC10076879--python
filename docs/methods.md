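# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Study design assumed

All stages assume a two-group design of matched case/control pairs from
the same subjects (in the motivating application: ectopic endometriosis
lesion tissue vs the same patient's eutopic endometrium). Group-wise
summaries (mean β per group, mean normalized count per group) are the
primary effect scales; the pairing is carried in the sample sheet
(`pair_id`) and is used only when the paired test is explicitly requested.

## Differential methylation

- **β values.** β = M/(M + U + offset) with offset 100, the standard
  regularized proportion for two-channel intensity data; β is bounded in
  [0, M/(M+offset)) ⊂ [0, 1). Pipelines that already have β matrices skip
  this step.
- **Quantile normalization** forces every sample column onto the common
  reference distribution (row-wise mean of per-column sorted values),
  preserving within-column ranks; tied entries receive the mean of the
  reference values their positions span. A single-column matrix is
  returned unchanged with a warning.
- **Test.** Two-sided Wilcoxon rank-sum, unpaired by default even though
  samples are paired: the reported effect scale is the difference of group
  means, which matches a group-wise test, and the unpaired test is robust
  to broken or incomplete pairing. `paired=True` switches to the
  signed-rank test. The exact null distribution is used when
  n₁ + n₂ ≤ 12 and the data have no ties; otherwise the normal
  approximation with midrank tie correction. **No continuity correction**
  is applied in the approximation: the rank-sum null is discrete, and at
  typical group sizes the correction stacks onto that discreteness to make
  null p-values visibly conservative (empirically, the null p-value KS
  distance from uniform at n = 10/group roughly halves without it). Exact
  and approximate paths agree to ~2 decimal places at the crossover sizes.
- **Calling rule.** Significant = raw p < 0.05 AND |Δβ| ≥ 0.2. The
  effect-size gate does most of the work: under the null at the default
  noise level, |Δβ| ≥ 0.2 is essentially never reached with n = 10/group,
  so the genome-wide called fraction stays well below 2% without relying
  on FDR control. BH-adjusted values are still computed and reported for
  reference. Hyper = higher in case, hypo = lower.

## Probe annotation

- Promoter := TSS1500 ∪ TSS200, the standard 450K convention.
- A probe's six-way region group collapses its (gene, class) annotations:
  none → Intergenic; only promoter classes → Promoter; one distinct
  non-promoter class → that class (Body reported as GeneBody); two or more
  distinct classes → MultipleLocations.
- Island relations are purely geometric: Island inside the interval,
  shores the 2 kb flanks, shelves the next 2 kb, OpenSea beyond; with
  several islands the nearest one decides, ties to the lower-coordinate
  island. Coordinates are 1-based inclusive (manifest convention); BED
  export converts to 0-based half-open.
- Region/island distributions of DM loci are reported per direction
  (hyper and hypo separately), each column summing to 1.

## Differential expression

A deliberately simplified per-gene NB Wald test — explicitly **not** a
DESeq2 reimplementation (no dispersion shrinkage across genes, no outlier
refitting), so the stage stays self-contained and fully testable:

- size factors by median-of-ratios over genes with positive counts in all
  samples;
- per-gene dispersion by method of moments, α = (s² − μ)/μ² per group,
  pooled across the two groups with df weights and floored at 1e-8;
- log2FC = log2((μ_case + ½)/(μ_control + ½)); the ½ pseudo-mean
  stabilizes low-count fold changes;
- Wald SE by the delta method under Var = μ + αμ²;
- two-sided p from a **t reference with n₁ + n₂ − 2 df** rather than the
  normal: with moment-estimated dispersion at few replicates the normal
  reference is markedly anti-conservative (null false-positive fraction at
  p < 0.05 near 0.09 at n = 5/group), while the t reference brings it to
  ≈ 0.05 without affecting power at the effect sizes of interest;
- BH adjustment; DEG gates padj < 0.05 and |log2FC| ≥ 1.

All-zero genes are excluded and listed in the result's
`attrs["excluded"]`. PCA QC operates on gene-centered
log2(normalized + 1) values via SVD, with signs fixed so each component's
largest-magnitude loading is positive.

## Integration

- One record per (gene, DM direction); the representative locus is the
  significant probe with maximal |Δβ| (ties → lower p → lexicographic
  probe id). A starburst-style scatter of genes needs one point per gene;
  max-|Δβ| is our rule, chosen to preserve the ranking criterion of the
  candidate tables.
- Promoter-related ⇔ the representative locus is annotated TSS1500/TSS200
  for that gene; "enhancer-related" is simply "not promoter" — no
  chromatin evidence is used or implied.
- Quadrants by sign: part 1 (Δβ<0, log2FC>0), part 2 (+,+), part 3 (−,−),
  part 4 (+,−); exact zeros fall on "boundary" and are excluded from
  quadrant counts. This numbering (part 1 = hypo-up, part 4 = hyper-down,
  the two anti-correlated quadrants) is a package convention constant.
- Region-stratified Pearson r between Δβ and log2FC with two-sided
  t-reference p on n − 2 df; groups with n < 3 or zero variance are
  reported as undefined and flagged.
- Candidate tables: top-k (default 15) by |Δβ| descending among records
  passing the expression gates (padj < 0.05, |log2FC| ≥ 1) in the
  hyper-down and hypo-up quadrants; ties by lower padj then gene symbol.
  Quadrant percentages are rounded half-even to one decimal.
- Both a quadrant-based and a direction-based (up/down) tally of
  promoter/enhancer DMGs are emitted; they answer different questions and
  are deliberately not reconciled.

## Enrichment

Hypergeometric upper tail P(X ≥ k), identical to the one-sided Fisher
exact test; `scipy.stats.hypergeom.sf` supplies a numerically stable
implementation. The universe is configurable (platform genes vs expressed
genes); this unstated background choice changes results more than any
other enrichment option, so it is an explicit flag rather than a default
buried in code. Gene sets arrive as GMT files; no pathway databases are
bundled or fetched.

## qPCR

ΔCt = Ct(target) − Ct(reference); ΔΔCt per sample is measured against the
arithmetic mean of control ΔCt, and fold = 2^−ΔΔCt, so the control group
has geometric-mean fold 1 by construction. Folds are invariant to any
constant shift applied to all Ct values. Group comparison: Welch's t when
both groups pass a Lilliefors-style KS normality check (parameters
estimated from the data; p ≥ 0.05 = normal; n = 3 uses a seeded
Monte-Carlo null since tabulated critical values start at n = 4),
otherwise Mann-Whitney. Stars: *** p<0.001, ** p<0.01, * p<0.05, ns.

## Synthetic-data generator

The generator emulates the matched-pair multi-omic design with planted,
recoverable structure:

- **Manifest**: genes placed on 5 synthetic chromosomes; probes allocated
  ~25% promoter, 40% genic, 5% multi-annotation, 30% intergenic, with CpG
  islands (300–2000 bp) over about half the TSSs plus free-standing ones;
  island relations derived geometrically from the intervals.
- **Methylation**: β ~ Beta(μφ, (1−μ)φ) with precision φ = 40 (≈ 0.08 SD
  at μ = 0.5 — a mid-range array-like noise level chosen for testability;
  no empirical dispersion was available to match). Planted probes shift
  the case-group mean by ± `delta_beta_effect` (default 0.3); base means
  are redrawn so shifted means stay inside (0, 1), clamping with a warning
  otherwise.
- **Counts**: NB with per-gene log-normal base means, log-normal library
  size factors (σ = 0.2), dispersion α = 0.05. Planted DEGs get
  ± `lfc_effect` (default 2) and their base means are drawn ≥ 100
  normalized counts so planted effects sit on adequately expressed genes.
- **Coupling**: every gene with a planted promoter DML becomes a coupled
  gene with log2FC = `coupling_strength` × (Δβ/`delta_beta_effect`) ×
  `lfc_effect`; at the default −1, promoter hypermethylation exactly
  depresses expression — the planted analogue of the promoter-repression
  signal the integration is built to detect. Coupling applies to promoter
  probes only.
- **Defaults** are a small matched study: 6 pairs (the methylation-array
  cohort size of the motivating design), 5,000 probes, 800 genes.
- **qPCR**: Ct tables for the strongest planted genes, with case ΔCt
  lowered by the true log2FC (one cycle per doubling) plus 0.3-cycle noise.
- All randomness flows from one seed through independent SeedSequence
  children per stage; identical configs are bit-identical.

What it does **not** emulate — and hence what passing tests do not show
about real data: probe-level spatial correlation and type-I/II probe
chemistry, cell-type composition and batch effects, within-pair
correlation of β values (pairs share labels but are drawn independently),
count outliers and sample-specific GC effects, and any realistic
gene-length or island-density distribution. Recovery rates here are upper
bounds for arrays of comparable noise, not estimates for patient data.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the null-calibration checks
at 10,000 probes (n = 10/group) and 2,000 genes (n = 5/group), and the
recovery checks at 4,000 probes / 800 genes (DM, coupling) and 2,000 genes
(DE) — sizes at which the Monte-Carlo bounds are stable across seeds while
the whole suite stays fast. The analysis drivers use 8,000 probes / 1,200
genes / 6 pairs.

## Known limitations

- The unpaired default discards the pairing information; the paired
  signed-rank option is provided but group-mean Δβ remains the effect
  estimate either way.
- Method-of-moments dispersion is noisy at n ≤ 5 per group; the t
  reference compensates on average but per-gene SEs remain rough, and no
  information is shared across genes by design.
- "Enhancer-related" is a naming convention for non-promoter loci, not an
  enhancer call.
- Multi-gene probes contribute one record per annotated gene, so a probe
  can represent two genes simultaneously.
- The percentage rounding in quadrant summaries is half-even at one
  decimal; totals, not percentages, are the authoritative counts.
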