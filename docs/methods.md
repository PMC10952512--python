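# Methods

## The analysis in one paragraph

Two locally adapted plant ecotypes (montane and alpine), sampled as two
independent ecotype pairs, are reciprocally transplanted so that every
genotype grows at both altitudes.  Gene-level RNA-seq counts over this
2 (pair) x 2 (ecotype) x 2 (environment) design let expression divergence be
decomposed into a **constitutive** component — genes DE between ecotypes in
*both* environments with a consistent direction, i.e. genetically fixed
divergence — and a **plastic** component — genes whose expression within one
ecotype shifts when that ecotype changes environment (a G x E signal).
Secondary analyses connect the expression classes to DNA-level signals:
exact hypergeometric tests for every set-overlap claim, GO-style
over-representation with directional z-scores, per-site Hudson/Bhatia FST
with top-5% outlier carriage, and population-private alleles as an ancestry
proxy.

## Statistical model

### Negative binomial group-means GLM

Counts are modeled as NB(mu, phi) with var = mu + phi mu^2.  Within one
ecotype pair the 2x2 (ecotype x environment) layout is fitted **saturated**:
one log-scale coefficient per cell, a log effective-library-size offset, no
cross-cell constraints.  Fisher scoring updates are independent across cells
in this parameterization, so all genes are fitted simultaneously as matrix
operations.  A cell contrast is tested by a likelihood-ratio test against a
model in which the two contrasted cells share a coefficient (the other cells
refit freely, though their estimates are unchanged in a saturated layout);
the deviance difference is referred to chi-square(1), and p-values are BH
adjusted per contrast.

This replaces a single all-samples model with interaction terms by per-pair
saturated fits.  For the four reported contrast families the two are
equivalent parameterizations of the full-interaction model restricted to a
pair; the one deliberate statistical difference is that dispersion is still
estimated **jointly across pairs** (the 8-cell design), which mirrors the
pooled-dispersion practice of the standard tooling.

### Dispersion estimation

Per-gene dispersions maximize the Cox-Reid adjusted profile likelihood
APL_g(phi) = l_NB(phi; y_g, mu_hat_g(phi)) - 1/2 log det(X^T W X), with
W the Fisher weights mu/(1 + phi mu); for the one-way layout the determinant
is the product of per-cell weight sums.  The common dispersion maximizes the
summed APL on a 31-point log grid over [1e-4, 4] refined by golden-section
search; per-gene maxima use the same grid with quadratic interpolation.
Shrinkage is linear on the log scale, log phi_tilde = (d0 log phi0 +
df_res log phi_g)/(d0 + df_res) with prior df d0 = 10 by default and
df_res = n_samples - n_cells.  Outlier-robust estimation (the `robust`
option of the reference tooling) is intentionally not reimplemented;
recovery, not bit-equality, is the design goal.  Cross-validation: on a
default-scale simulated matrix, edgeR 4.0 `estimateDisp(robust=TRUE)`
returns a common dispersion agreeing with this implementation to four
decimals (0.1932).

### Normalization and filtering

Genes are kept when their mean raw-library CPM across all samples is
strictly greater than 1 (the filter precedes normalization; the ordering is
a documented choice since the procedure's order is ambiguous in prose
descriptions).  TMM factors use the sample whose upper-quartile CPM is
closest to the mean upper quartile as reference; per sample, M and A values
over genes expressed in both are doubly trimmed (30% by M, 5% by A) and
combined with inverse delta-method-variance weights; factors are rescaled to
geometric mean 1.

### Classification thresholds

* constitutive: BH-adjusted p < 0.05 in both per-environment ecotype
  contrasts and matching fold-change sign (zero sign excluded);
* plastic: BH-adjusted p < 0.05 in the within-ecotype altitude contrast and
  |log2FC| >= log2(1.5) ~ 0.585.  The fold-change gate defaults to the
  linear-FC reading ("minimum fold change of 1.5"); the stricter log2-scale
  reading (|log2FC| >= 1.5) is available via `fc_scale="log2fc"` because the
  source material states both variants in different places.  Fold changes
  are computed from fitted cell CPMs moderated by a prior count of 0.5.
* The cross-environment Spearman correlation is computed over genes DE in at
  least one environment (`union_de`), with `all_tested` as the alternative.

### Overlap statistics

Every set-overlap claim is the exact hypergeometric upper tail
P(X >= k | N, K, n), computed in log space via log-gamma and logsumexp and
summed from the shorter tail side, so p-values far below the double-precision
underflow of naive products (1e-147 and smaller) retain full relative
precision.  Chance expectations are n K / N, with half-away-from-zero
rounding for printed integers.  The default universe is the set of genes
surviving the CPM filter; per-test override exists because printed expected
counts in the source analyses are not all consistent with a single universe.

### Enrichment

Classic one-sided Fisher (hypergeometric tail) per GO-style term on
annotations propagated by the true-path rule, BH adjusted across tested
terms, terms under 5 universe genes skipped.  The decorrelation algorithms
of topGO (weight/elim) are out of scope by design.  The per-term direction
score is z = (up - down)/sqrt(up + down) over the term's study genes with
nonzero log2FC — the convention of GO-plotting tools; if the intended
statistic ever differs, only `term_zscore` changes.

### Population genetics

Per-site FST uses the Bhatia et al. sample-size-corrected Hudson estimator
(numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1), denominator
p1(1-p2) + p2(1-p1)); sites need >= 4 non-missing alleles per population.
Fixed differences give exactly 1 for any sample size; negative values are
retained (clamping would distort the quantile threshold).  The top-5%
threshold is the linear-interpolation empirical quantile over all defined
per-site values — including sites outside genes, which shape the
distribution but cannot mark a gene.  Gene-level summaries also expose the
ratio-of-averages sum(N)/sum(D), the standard Hudson aggregate, and it is
this aggregate that recovers a generative F in simulation.  The reference
analyses estimated the same quantity from genotype likelihoods in ANGSD;
computing it from called genotypes is the desk-scale stand-in, and VCFs are
assumed pre-filtered for depth/quality.

A site is private to population P when, after excluding sites whose missing
fraction exceeds `max_missing` (default 0: none allowed), one allele — ref
or alt — has count >= 1 in P and count 0 in every other population.  Counts
are normalized by the population's sample number; the MAF of a private site
is the minor-allele frequency within the carrier population.

## The synthetic world

The generator emulates the modeled experiment, not any particular dataset:

| parameter | default | why |
|---|---|---|
| genes | 16000 | order of the filtered transcriptome |
| replicates | 5 per cell; (pair 3, montane ecotype, alpine environment) = 2 | the surviving-sample structure of the field experiment |
| library sizes | U(5e5, 1.5e6) | bulk RNA-seq per-sample depth range |
| baseline log2 mean | N(5, 2) | wide, right-skewed expression distribution |
| dispersion | log-uniform [0.05, 0.5] | typical bulk NB dispersions |
| constitutive / plastic-montane / plastic-alpine fractions | 0.02 / 0.03 / 0.01 | rare effects; montane-biased plasticity is the observed direction |
| planted \|log2FC\| | N(1.5, 0.5), random sign | moderate effects around the FC gate |
| variant sites | 20000; 5% outliers at F = 0.6 vs background F = 0.1 | Balding-Nichols, closed-form E[FST] ~ F |
| outlier clustering | 1000 outlier sites in 100 designated genes | see below |
| private sites | 250 per montane, 500 per alpine population; carrier freq U(0.05, 0.45) | the 2x alpine excess is the ancestry-proxy pattern under test; 250 is a free choice giving stable per-population counts |
| genotype samples | 10/10 (pair 1), 7/10 (pair 3) | the genotyped sample sizes of the modeled study |
| annotation | 300 terms, 0-2 parents each, background rate 0.02; 10 planted leaf terms of 30 genes, half from the constitutive pool | small GO-like DAG |

Randomness comes from per-module child streams of one seed
(`default_rng([seed, module_key])`), so regenerating counts never perturbs
genotypes.

Two generator choices deserve their rationale:

* **Outlier-site clustering.**  Balding-Nichols frequencies at F = 0.6 are
  U-shaped: most sites drift toward fixation for the *same* allele in both
  populations and carry little per-site FST signal; only ~1/3 individually
  exceed an empirical top-5% threshold.  A planted outlier gene is therefore
  only reliably detectable when it carries several divergent sites, as real
  selective sweeps do.  Outlier sites are drawn inside a 100-gene designated
  subset (~10 sites per gene) rather than spread over every eligible gene.
* **Leaf-term planting.**  Under the true-path rule a term inherits every
  descendant's annotations, so a "planted enriched" term high in the DAG is
  not actually enriched once propagated.  Planted terms are drawn from DAG
  leaves, where enrichment signal lives in practice.

What the generator does **not** emulate: GC/length biases, batch effects,
correlated genes, linkage disequilibrium within genes, genotyping error, or
annotation noise.  A green recovery test therefore establishes correctness
of the estimators under the stated model, not robustness to real-data
artifacts.

## Numerical choices

* IRLS convergence at max |coefficient change| < 1e-8, 50 iterations,
  steps clipped to +/-10; all-zero cells floor at a relative rate of 1e-8.
* NB deviance uses log1p forms so the Poisson limit stays exact to ~1e-4
  against a closed-form Poisson oracle at phi = 1e-8.
* A negative LRT statistic beyond -1e-6 raises (optimizer-bug tripwire);
  within tolerance it clamps to 0.
* BH is the standard step-up with no tie handling needed; ties in Spearman
  use average ranks; TMM trimming uses average ranks of M and A.
* The PCA QC runs on gene-centered log2(CPM + 0.5) with a full SVD.
* Result tables render floats at 6 significant digits and sort by the first
  column, making reruns byte-identical.

## Known limitations

* Sensitivity of the constitutive classification on the default synthetic
  world tops out near 70% for planted |log2FC| >= 2 because the
  both-environment intersection squares the per-contrast power loss on
  low-expression genes (~3 counts/sample); edgeR reproduces the same ceiling
  on identical data.  This is a property of the procedure at n = 5, not of
  the implementation.
* Dispersion shrinkage uses a fixed prior df; no trended or outlier-robust
  empirical Bayes.
* FST from called genotypes understates the information a
  genotype-likelihood method extracts at low coverage.
* The chi-square(1) reference for the LRT is slightly conservative at very
  low counts (visible in the null-calibration band [0.03, 0.08]).
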