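# Methods

This note describes the statistical procedures implemented in `thlineage`,
the design choices made where the procedure was genuinely open, what the
synthetic data generator does and does not emulate, and the package's known
limitations.

## Study design being modelled

Four CD4+ T-helper subtypes are profiled in replicate at an early
differentiation time point: naive precursors (Thp), cells activated without
polarizing cytokines (Th0, the activation control), and cells polarized
toward Th1 (IL12) or Th2 (IL4). Expression is measured on multiple
platforms of two kinds: array-like platforms yielding continuous log2
intensities, and a sequencing platform yielding non-negative integer
counts. A feature (protein-coding gene or lncRNA) is *lineage-specific*
when it responds to polarization but not to activation alone: DE in Thp vs
Th1 only (or Thp vs Th2 only) and not in Thp vs Th0.

## Presence calling

Log-scale expression pooled over a whole platform ("chip-wide") is bimodal:
a low-mean component of unexpressed/background features and a high-mean
component of genuinely expressed ones. We fit a two-component Gaussian
mixture by EM and call a feature *present* in a subtype only if **every**
replicate of the subtype is more likely to originate from the high-mean
component.

Numerical choices (the published procedure says only "standard EM"):

- Initialization splits responsibilities at the pooled median; `n_starts=5`
  restarts jitter the split quantile uniformly in (0.25, 0.75). The best
  final log-likelihood wins.
- Convergence: relative log-likelihood improvement below `tol=1e-8`, at
  most `max_iter=500` iterations; non-convergence returns a flagged fit
  with a warning rather than an error.
- A standard-deviation floor of `1e-3` (log2 units) prevents component
  collapse onto a point mass.
- "Higher likelihood for the high-mean component" is read as posterior
  responsibility > 0.5, i.e. mixture-weighted densities. An unweighted
  density comparison is available (`rule="density"`); the two differ only
  when the mixing weights are far from 1/2 near the decision boundary.
- Fewer than 10 finite values, or zero variance, is a degenerate input and
  an error.

One fit is shared by all samples of a platform (pooled values); per-array
fitting would also be defensible but would let presence thresholds drift
between replicates of the same subtype.

Illumina-style arrays provide per-probe detection p-values instead; a
feature is present when detection p < 0.01 (strict) in all replicates.

Duplicate probes mapping to one gene are collapsed by retaining the probe
with the largest inter-quartile range across all samples; exact ties go to
the lexicographically smallest probe identifier so the operation is
deterministic.

## Differential expression

The package's contribution is the thresholds, the presence refinement and
the cross-platform consensus — not the DE engines — so the tests are
reference implementations with a pluggable table interface (externally
produced tables in the same TSV schema are accepted).

**Intensity platforms.** Moderated unpaired t-test with empirical-Bayes
variance shrinkage. Per gene, the pooled two-group variance s² (df = n1+n2−2)
is shrunk toward a prior variance s0² with prior degrees of freedom d0:
posterior variance = (d0·s0² + df·s²)/(d0 + df), and the t statistic is
referred to a t distribution with df + d0 degrees of freedom. (d0, s0²) are
estimated by moment matching: under the scaled-inverse-chi-square hierarchy
the marginal of s²/s0² is F(df, d0), and matching the squared coefficient of
variation of the observed s² to that of the F distribution gives d0, then
the mean gives s0². When the observed spread is at or below the pure
chi-square expectation, d0 is capped at 1e6 (effectively complete
shrinkage); d0 may also be pinned (0 recovers the ordinary equal-variance
t-test).

**Count platform.** Counts are normalized with median-of-ratios size
factors: per sample, the median over all-positive genes of
count/geometric-mean, rescaled so the factors have geometric mean exactly 1.
The variance-stabilizing transform is log2(normalized + 1) — monotone,
parameter-free, and adequate for mixture presence calling and correlation
work. DE on the count platform is the moderated t applied to these
stabilized values; the reported fold change is therefore a "modified" log2
fold change on the stabilized scale. Because of the +1 pseudocount, global
depth scaling cancels only asymptotically (error ~1/count); per-sample
depth differences are absorbed by the size factors as usual.

**Thresholds.** A feature is DE when BH-adjusted p < 0.05 **and**
|log2FC| > 1, both strict, matching the printed rules. Gene calls are then
*refined* by presence: the call survives if the feature is present in at
least one of the two compared groups. The published rule does not state
which group(s); "either" is the default and "both"/"test"/"none" are
switchable. lncRNA tables are not refined by default.

## Cross-platform consensus and lineage classification

A feature has a consensus DE call for a comparison when it is DE on at
least two platforms with the same fold-change sign (a feature missing from
a platform's table contributes no vote, since platforms differ in
annotation coverage; an opposite-sign quorum voids the consensus). A
feature is Th1-specific when DE in Thp vs Th1, not DE in Thp vs Th0, and
not DE in Thp vs Th2 — the last exclusion implements "uniquely", and makes
the Th1 and Th2 lists disjoint by construction. The same classification run
on the sequencing platform alone gives the "novel" gene list and the lncRNA
lists (lncRNAs are only measured by sequencing in the modelled design).

## Mark enrichment randomization test

Enhancer marks are counted within ±125 kb of the TSS, active-promoter
marks within ±2.5 kb. These windows are symmetric and therefore
strand-independent. A mark overlapping the windows of two features in the
set counts once (deduplicated; per-feature counting is switchable, as the
original counting convention is not specified). The zero-width window
degenerates to the single-bp TSS interval.

The null distribution draws `n_iter` (default 10,000) feature sets of the
same size uniformly without replacement from the universe excluding the
target ("anywhere else"), recounting the overlap each time. The empirical
p-value is (r+1)/(n+1) with r = #{null ≥ observed}: unbiased-conservative
and never exactly zero, so the smallest reportable value at n=10,000 is
just under 1e-4. The null preserves only set size — not chromosome,
expression level or gene length.

## lncRNA characterization

- **Vicinity rule**: a lncRNA pairs with a gene when its body overlaps the
  window from 5 kb upstream of the gene body to 30 kb downstream, oriented
  by the *gene's* strand (body-anchored). Whether the rule was TSS- or
  body-anchored, and strand-aware, was not stated; both are switchable.
- **Co-expression**: Pearson correlation on the count platform's
  variance-stabilized values across all samples and subtypes; an edge
  requires |r| > 0.9 strictly. Constant profiles have undefined r and are
  excluded with a warning.
- **GO attribution** (guilt-by-association): for each lncRNA, its
  co-expressed protein-coding genes form the study set; the universe is the
  expressed (present in ≥1 subtype) protein-coding genes. Each GO term is
  tested with the one-sided Fisher exact test (hypergeometric upper tail)
  after true-path propagation of annotations. The topology-aware *elim*
  algorithm processes terms children-before-parents and removes the genes
  of any term with p < 0.01 from its ancestors before they are tested;
  `classic` (no elimination) is the comparator. Terms annotating fewer than
  3 universe genes are skipped (degenerate tables). Terms with p < 0.01
  (strict, unadjusted — mirroring the attribution rule) are assigned to the
  lncRNA; BH correction is available behind a flag.
- **Pair trend**: per vicinity pair, Pearson r across all samples, with the
  mean r and fraction positive as summary.

## Disease-SNP enrichment

SNPs with association p > 1e-5 are excluded (p = 1e-5 exactly is kept). A
gene is associated with a SNP's trait when the SNP lies within ±100 kb of
the gene *body* (distance 0 inside; strand-independent); a gene hit by
several SNPs of one trait counts once. Trait enrichment in a lineage set is
the hypergeometric upper tail P(X ≥ k) for k overlaps out of n lineage
genes, K trait-associated genes, N universe genes. The universe is the
expressed feature set of the same class (genes or lncRNAs) — enrichment
relative to the tested pool, not the whole annotation — and is switchable.
No multiple-testing correction across traits by default.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the demo-scale
study conditions: 10,000 genes and 200 lncRNAs on one 250-Mb synthetic
chromosome, 4 subtypes × 3 replicates on three platforms (two intensity,
one count), 300 Th1- and 300 Th2-specific genes and 30+30 lncRNAs planted
with |log2 effect| = 2.

- Expression is bimodal by construction: per platform, expressed features
  draw a baseline from N(9, 1) (log2), unexpressed from N(4, 1), with 70%
  expressed; replicate noise is N(0, 0.25). Planted features are forced
  expressed, and shifted by ±2 in the matching polarized subtype **only**
  — never in Th0 — with the sign shared across platforms. Counts are
  negative-binomial with mean 2^signal × a per-sample log-normal depth
  factor (sd 0.3) and common dispersion 0.05 (per-gene dispersion is a
  config extension, not a default).
- Half of each lineage's planted lncRNAs are placed inside the vicinity
  window of a planted same-lineage gene and inherit that gene's effect
  sign (cis co-regulation) — this produces the positive pair-expression
  trend; remaining features land uniformly in unoccupied sequence. Gene
  bodies never overlap, keeping vicinity semantics unambiguous
  (overlapping-gene behaviour is exercised with hand-built fixtures in the
  tests). lncRNA biotype labels are drawn with GENCODE-like proportions
  but are labels only — an "antisense" lncRNA does not physically overlap
  a gene.
- Enhancer/promoter marks: 3,000 background intervals per lineage and
  class, uniform over the genome; within planted same-lineage gene TSS
  windows the density is multiplied by 5 (extra marks drawn Poisson).
- SNPs: 2,000 background positions, ~half with association p ≤ 1e-5 (log10
  p uniform); each configured cluster trait adds 30 significant SNPs
  within ±100 kb of planted genes of one lineage (traits alternate Th1,
  Th2).
- GO: a 3-level random is_a DAG (5/12/25 terms) under a single root;
  terms annotate 10–30 random genes, except one planted leaf term whose
  genes are 25 planted Th1 genes — these share the polarized expression
  pattern and are therefore co-expressed with the planted Th1 lncRNA,
  which lets guilt-by-association recover the term.

Everything is driven by one `numpy` Generator seeded from the config, so a
given config is byte-reproducible after serialization. The pipeline derives
per-stage seeds from the root seed by hashing the stage name, so stages are
independently reproducible.

**What the generator does not emulate**: probe-level array artifacts,
quantile/RMA normalization residue, per-gene dispersion trends, correlated
replicate structure (batch effects), linkage disequilibrium among SNPs,
realistic chromosome structure or multi-chromosome synteny (multiple equal
chromosomes are available behind a flag), and physically overlapping
genes. Passing the planted-truth tests therefore demonstrates the
correctness of the decision rules and statistics under their model
assumptions, not performance on real microarray/RNA-seq data.

## Problem sizes used in tests and acceptance runs

Unit tests run on a 400-gene / 40-lncRNA configuration on 20 Mb (the
planted structure is otherwise identical); the end-to-end checks and the
acceptance script run the full default (10,000-gene) configuration with
n_iter = 10,000 randomization draws. Null-calibration checks use 200
repeated datasets at 199 draws each, and the planted-enrichment detection
check uses 100 datasets at 999 draws — sizes chosen so the granularity of
the empirical p-value (1/(n_iter+1)) is well below the thresholds being
verified.

## Known limitations

- The DE engines are reference implementations: results will differ in
  detail from limma's (log-variance moment matching, trend fitting) and
  DESeq's (GLM, dispersion shrinkage, outlier handling), though the
  downstream thresholds, refinement, and consensus are the published rules.
- The randomization null matches set size only; GC-, length- or
  expression-matched nulls are out of scope.
- The elim implementation covers the elim algorithm only (no weight /
  parentchild variants), with is_a edges.
- Empirical p-values are granular at 1/(n_iter+1) and, with discrete
  overlap counts, slightly conservative at ties.
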