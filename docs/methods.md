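# Methods

This note documents the models, the synthetic cohorts, the numerical
choices, and the design decisions behind `orgenrich`. It is written for a
reader who wants to know exactly what each function computes and what the
passing test suite does — and does not — establish about real data.

## Trait prioritization

Age-related diseases are ranked from long-form period-prevalence tables
(disease, median onset, age-band lower bound, prevalence). A disease
qualifies when its median onset exceeds `onset_min` (default 50 years);
its score is the summed period prevalence over bands whose lower bound is
at least `age_min` (default 50; bands are left-labelled in the source
data, so "above 50" is read as lower bound ≥ 50, with a strict `>` rule
available by configuration since either reading is defensible). Ties are
broken lexicographically by disease identifier so the ranking is
deterministic under row permutation. Candidate GWAS are then filtered on
heritability evidence with the strict rule h²/se > 4; the manual mapping
from epidemiological disease labels to GWAS phenotypes is a user-supplied
table, not something the package infers.

## Gene-set construction

Localization evidence arrives as integer confidence scores 0–5 per
(gene, compartment). Assignments with score > 2 (i.e. ≥ 3 on the integer
scale) are kept; each gene joins every compartment achieving its maximal
remaining score, so ties produce multiple memberships. Compartments with
≤ 240 members are dropped (strictly greater than 240 survives — the
boundary is covered by a test), and the mitochondrion can be replaced
wholesale by a curated inventory. Nuclear sub-compartments follow the
same scoring rules; nucleoplasm is made exclusive of the other nuclear
subsets *before* the size filter (the alternative order is not
distinguishable from the available descriptions; exclusivity-first is the
more conservative choice because it never lets removed genes prop up the
nucleoplasm set size), the chromosome set is merged with the curated
transcription-factor list, and any nucleus member in none of the subsets
falls into `other_nucleus`. TF partitions use τ ≥ 0.76 for
tissue-specific vs broad (the threshold itself comes from the nadir
detector below, with 0.76 as the fixed fallback), age terciles by stable
phylostratum rank over the TF list itself, and DNA-binding-domain groups
(KRAB zinc finger / other zinc finger / non-zinc-finger).

## Catalog screen and the enrichment count

Trait-associated gene sets keep genes with any association below 5e-8,
deduplicated, and traits with more than 30 such genes. Each trait yields
a 2×2 table (in-set/out-set × associated/not) tested with a two-sided
Fisher exact test; the p-value is the classical sum of hypergeometric
point probabilities not exceeding the observed table's probability, with
a 1e-7 relative slack for floating-point ties (matching the convention of
standard implementations, which serve as the independent reference in the
tests). The odds ratio is the sample odds ratio without continuity
correction; degenerate margins give p = 1 and a null verdict. BH
correction at FDR 0.1 is applied across the tested traits.

`N_enrich` counts traits with odds ratio strictly above 1 (ties excluded;
a `p<0.05`-and-OR>1 variant is exposed as an option). The empirical null
redraws same-size gene sets uniformly without replacement from the
universe; the one-sided empirical p uses the add-one estimator
(1 + #{null ≤ observed}) / (1 + n_samples), which cannot return zero from
finite sampling at the cost of a slight conservative bias (the plain
proportion is available by flag).

Because `N_enrich` is integer-valued over the tested traits, its null
distribution is a step function: with only ~24 traits the steps near the
5% tail are 3–5 percentage points wide and a tail probability is barely
defined. The calibration experiment therefore simulates 100 traits with
heterogeneous catalog sizes, chosen from this discreteness argument so
that Pr(emp_p ≤ 0.05) is a meaningful property of the estimator. Since
uniformly random targets follow exactly the null-sample distribution, a
single shared null (2000 draws) is valid for all 500 calibration targets.

## Competitive regression

Ordinary least squares of gene Z on [intercept, membership, length, SNP
density (per kb, so the covariate is unit-stable across gene lengths),
inverse MAC, and the log of each], with the one-sided upper-tail t
p-value on the membership coefficient. A control superset restricts the
analyzed genes by default (the competitive background); including the
superset as an indicator covariate instead is available. Rank-deficient
designs raise an error naming the collinear columns. Constraint
conditioning residualizes the membership indicator on
[1, LOEUF, log LOEUF] before the main fit; genes with missing or
non-positive LOEUF are dropped and counted. When membership is
sample-orthogonal to LOEUF the residualization only recenters the
indicator, which leaves the coefficient, its standard error and p-value
unchanged — the no-op property the tests check.

The subsampling power framework draws uniform subsamples of a source set
at sizes {350, 800, 1105, 1523} by default and reports the fraction of
trials reaching significance with a Wilson 95% interval. The significance
rule is a plain p-threshold (nominal α, or a BH threshold computed from a
full analysis batch and passed in). One arithmetic fact matters when
interpreting power curves: with a standardized shift δ the non-centrality
at set size m in an N-gene universe is ≈ δ·√(m(1−m/N)), so δ = 0.3
already gives essentially unit power at m = 350 (ncp ≈ 5.6). The
monotone-power *shape* of the curve is therefore exercised in the unit
tests at δ = 0.05 — inside the responsive regime — while the δ = 0.3
recovery experiment checks detection and non-decreasing power across
sizes, where the curve is saturated by design.

## Tissue specificity and the eQTL landscape

τ follows the standard formula (x̂ᵢ = xᵢ/maxᵢxᵢ; τ = Σ(1−x̂ᵢ)/(n−1));
genes with maximal cross-tissue TPM below 1 receive no τ. The bimodal
threshold detector histograms τ on [0, 1] (50 bins), smooths with a
3-bin moving average, takes the primary mode plus the tallest peak at
least bins/10 away (so jitter inside one mode is not mistaken for
bimodality), and returns the midpoint of the middle minimum-density bin
between them; unimodal input falls back to a supplied fixed threshold
(default 0.76) with a warning. Representative-tissue deduplication keeps
one tissue per correlated class (a configurable mapping — no tissue names
are hard-coded); τ, the eQTL tissue count (q < 0.05, strict) and the
expression tissue count (TPM > 5, strict) are computed on the retained
subset. The landscape regression is OLS of the eQTL count on
[organelle indicator, expression count, τ, log length, length] with a
two-sided test on the indicator; an exact fit (residual standard
deviation below 1e-10 of the response scale) is reported as β = 0, p = 1
rather than a 0/0 t-statistic.

Tissue-expressed sets take the ceiling of top_fraction × n_genes genes
per tissue by the supplied t-statistic (ceiling keeps "top 10%"
consistent with rounded published set sizes), ties broken by identifier.

## mtDNA association

QC order: sample call-rate filter first, then variant QC (exclusion list,
any heterozygous call, within-array-type call rate < 0.95 where a variant
absent from one array is judged on its own array only, fewer than 20
carriers — assessed after sample QC), then per-pair expected-case filter
for binary traits (carriers × case fraction ≥ 20, the natural reading of
an expected count). Covariates are 20 nuclear PCs, sex, age, age², sex·age,
sex·age²; an array-type indicator is available for linear models but
omitted for logistic fits by default because array-specific variants
separate completely on it.

Firth logistic regression maximizes ℓ(β) + ½·log det I(β) by Newton
iteration on the modified score U*(β) = Xᵀ(y − p + h(½ − p)) with
step-halving on the penalized likelihood; convergence when the largest
modified-score component falls below 1e-6 (covariates are standardized
internally for conditioning — the genotype column is left raw so its
coefficient keeps its scale — and a step below 1e-10 on a likelihood
plateau also counts as converged), with a 100-iteration cap and a
convergence flag on the output. Wald standard errors come from the
penalized information at the optimum (a penalized-likelihood-ratio test
is a possible alternative; Wald is the default because it is what the
standard large-cohort pipelines report). mtDNA-wide significance is
0.05 / (number of tested phenotype-variant pairs).

## Latent-normal correlations

Tetrachoric: thresholds fixed at the inverse normal of the marginal
prevalences (two-step), then the latent ρ maximizes the multinomial
likelihood of the 2×2 table over (−0.999, 0.999) by bounded scalar
minimization (xatol 1e-6) with the bivariate-normal rectangle probability
from standard quadrature; the standard error is the inverse observed
information at the optimum, by central second difference with step 1e-4.
Biserial (not point-biserial): the Pearson correlation of the binary and
continuous trait is rescaled by √(p(1−p))/φ(threshold), clipped to
[−1, 1]. p-values are normal approximations on estimate/se throughout.
Pairs use pairwise-complete observations, need at least 10 of them, and a
single-class binary trait skips the pair with a warning.

Trait ordering takes the element-wise absolute correlation matrix, the
eigenvector of largest-magnitude eigenvalue, flips its sign so the
largest-magnitude loading is positive, and sorts by descending loading
with ties broken by label (the sign and tie conventions are package
choices; any fixed convention gives a reproducible figure layout). The
shared Bonferroni cutoff is α / (C(n_g,2) + C(n_p,2)); with 24 traits in
the genetic arm and 21 in the phenotypic arm this is 0.05/486 ≈ 1.03e-4.

## Constraint summaries

Decile boundaries are the ⌈qn⌉-th order statistics (lower empirical,
type-1 quantiles) of the full gene table at q = 0.1, …, 0.9 — determinate
on ties and partitioning the table into deciles whose sizes differ by at
most one. A set's lowest-decile proportion uses LOEUF ≤ the first
boundary with a Wilson 95% interval; distribution summaries report the
set mean with a seeded percentile bootstrap (2000 resamples).

## Synthetic cohorts

The generators are pure functions of a `SimConfig` (seeded substreams per
generator), and their defaults are the study conditions: an 18,000-gene
universe (the protein-coding regime matching set sizes of 350–1523), 24
traits, 49 tissues grouped into classes with correlated subtypes, a
planted 1523-gene set with standardized Z shift 0.3, and a case fraction
of 0.25. Gene covariates are log-normal lengths and SNP densities,
inverse MAC as 1/MAC for MAC uniform on {1..5000}, and LOEUF from a
scaled beta on (0, 2]. mtDNA carrier counts are log-uniform between 20
and 0.1·n_samples (so QC retains them), with two array batches,
missing-completely-at-random calls at batch-specific rates, and a
liability-threshold binary phenotype — consistent with the latent-normal
model the tetrachoric estimator assumes. The planted mtDNA effect in the
recovery experiment is sized analytically for 90% power at the scan's
Bonferroni threshold for the rarest QC-passing variant (20 carriers), so
detection does not depend on the randomly drawn carrier count.

What the synthetic data does *not* emulate: linkage disequilibrium and
SNP-level architecture (gene Z-scores are drawn directly, so the
covariates are confounders only when a leakage slope is planted),
relatedness and population structure (PCs are pure noise), genuine
biological correlation between localization, expression and constraint,
and imputation artifacts. Passing tests therefore establish that the
statistical machinery is correct and calibrated under its own model
assumptions — not that those assumptions hold in any particular cohort.

## Experiment sizes

The calibration and recovery experiments (`orgenrich.calibration`, driven
by the acceptance script and tests) use: all 2×2 tables with margins ≤ 12
for Fisher agreement; 50 random small designs for the OLS oracle; an
8-observation dataset with six rounds of 41×41 grid refinement for the
Firth oracle; 500 targets against a 2000-draw shared null (100 traits,
4000 genes) for the enrichment-count calibration; 500 replicates at
18,000 genes for the competitive type-I rate; 5 × 213 variants at 4000
samples for the null mtDNA median chi-square; 100 replicates each for the
planted-enrichment and planted-mtDNA recovery; 25 replicates per ρ in
{−0.6, 0, 0.3, 0.8} at n = 50,000 for tetrachoric recovery; and 200
random 200-gene sets for the decile proportion. These sizes keep each
experiment's Monte Carlo error well inside the tolerance it is checked
against while the whole battery completes in a few minutes on one CPU.

## Known limitations

- The Fisher screen and enrichment count treat trait catalogs as fixed
  gene lists; correlated traits are not modelled in the null.
- The competitive regression assumes homoscedastic gene Z residuals; with
  LD-induced correlation between nearby genes the nominal standard errors
  would be anti-conservative (the upstream tools this layer consumes
  correct for that).
- Biserial standard errors are delta-method approximations; for very
  extreme prevalences the normal-approximation p-values degrade.
- The tau threshold detector assumes a genuinely bimodal distribution;
  flat or multi-modal inputs fall back to the fixed threshold.
- Firth p-values are Wald-based; penalized-likelihood-ratio tests would
  be more accurate at extreme carrier counts.
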