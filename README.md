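# methexpress

Integrated differential DNA-methylation and gene-expression analysis for
matched case/control tissue designs, built around the study design used in
ovarian endometriosis: ectopic (lesion) endometrial tissue paired with the
same patient's eutopic endometrium, profiled on a 450K-style methylation
array and by RNA-seq, then integrated at the gene level to nominate
candidate genes whose expression change is plausibly driven by promoter
methylation.

It is written for epigenomics analysts who have (or want to emulate) such a
paired multi-omic design: a β-value matrix plus probe manifest on the
methylation side, a gene-level count matrix on the expression side, and
optionally gene-set collections (GMT) and qPCR Ct tables for validation.
A synthetic-data generator with planted, recoverable effects makes every
stage testable without any patient data.

## Method

**Differential methylation.** Methylation per probe is the β value,
β = M/(M + U + 100) ∈ [0, 1). After optional quantile normalization and
Pearson-correlation QC, each probe is tested case vs control with the
two-sided Wilcoxon rank-sum test (exact for small pooled sizes without
ties, signed-rank available for paired designs). A locus is differentially
methylated (DML) when the raw p < 0.05 **and** |Δβ| ≥ 0.2, where
Δβ = mean β(case) − mean β(control); BH false-discovery rates are reported
alongside. Probes are annotated to region classes (TSS1500, TSS200, 5'UTR,
1st exon, body, 3'UTR), a six-way region group, and a CpG-island relation
(island; shores = 2 kb flanks; shelves = next 2 kb; open sea).

**Differential expression.** A deliberately simplified negative-binomial
Wald test: median-of-ratios size factors, per-gene method-of-moments
dispersion α under Var = μ + αμ², Wald statistic on
log2((μ_case + ½)/(μ_control + ½)) via the delta method, two-sided p from a
t reference with n₁ + n₂ − 2 df, BH adjustment. DEGs satisfy padj < 0.05
and |log2FC| ≥ 1.

**Integration.** Significant DMLs join the DE table by gene symbol (a
gene's representative locus is its max-|Δβ| significant probe). Genes
whose representative locus lies in TSS1500/TSS200 are promoter-related
DMGs, all others enhancer-related. Within each region group, Pearson r
between Δβ and log2FC quantifies the methylation-expression relation; each
gene falls into a quadrant of the (Δβ, log2FC) plane — part 1 = hypo-up,
part 2 = hyper-up, part 3 = hypo-down, part 4 = hyper-down — and candidate
tables list the top-15 hyper-down and hypo-up genes ranked by |Δβ|, with a
user-supplied exclusion list for previously reported genes. Gene lists are
tested for over-representation with the hypergeometric upper tail
(≡ one-sided Fisher exact). qPCR validation uses the 2^−ΔΔCt method with a
normality-driven choice between Welch's t and Mann-Whitney.

## Worked example

The `analysis/` scripts run the whole workflow on synthetic data (8,000
probes, 1,200 genes, 6 matched pairs; 640 planted DMLs at |Δβ| = 0.3, 60
planted DEGs at |log2FC| = 2, and 155 promoter-coupled genes whose
expression shift is −1 × their promoter Δβ effect):

```bash
python analysis/01_simulate.py                  # writes results/data/
python analysis/02_differential_methylation.py
python analysis/03_differential_expression.py
python analysis/04_integration.py
python analysis/05_enrichment.py
python analysis/06_qpcr.py
```

With the default seed (42) this prints, among other things:

```
633 significant DM loci of 8000 probes (315 hypermethylated, 318 hypomethylated)
planted-DML recall: 98.9% (640 planted)
215 DEGs of 1200 genes tested (109 up, 106 down in the case group)
planted-effect recall: 100.0%; false-discovery proportion among calls: 0.000
         Promoter  -0.944641 4.642087e-72      147
promoter-related DMGs in part 4 (hyper-down): 69/147 (46.9%)
```

i.e. the DM stage recovers essentially all planted loci at the stated
gates, the DE stage recovers all planted expression effects without false
calls, and the integration recovers the planted biology: promoter
methylation correlates strongly negatively with expression (r = −0.94)
while non-promoter groups show no systematic relation, and nearly half of
promoter-related DMGs land in the hypermethylated-downregulated quadrant.
The qPCR stage then confirms each assayed candidate's planted fold change
(e.g. mean fold 4.19 for a planted log2FC of +2, `***`).

The same workflow runs on real inputs via the CLI: `methexpress simulate |
dm-call | de-call | integrate | enrich | qpcr | pipeline` (see
`methexpress --help`).

Two 15-row candidate tables (hypermethylated-downregulated and
hypomethylated-upregulated genes, with probe, group-mean β values,
β change, island relation, log2FC and padj) ship with the package as
worked-example fixtures: `methexpress.pipeline.load_fixture_tables()`.

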