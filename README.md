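# orgenrich

Do loci encoding organellar proteomes carry more age-related-disease
heritability than expected? `orgenrich` is a reusable pipeline for asking
that question with gene-set methods: it builds organelle gene-sets from
subcellular-localization evidence, screens them against a GWAS catalog,
tests competitive heritability enrichment on gene-level association
statistics, models tissue specificity and the cis-eQTL landscape, runs an
mtDNA-wide association scan, estimates latent-normal trait correlations,
and summarizes gene constraint — with a first-class synthetic-data module
that plants known effects so every stage can be validated end to end.

It is aimed at statistical geneticists who want the *set-level* machinery
(covariate-adjusted competitive tests, empirical nulls, QC rules,
latent-correlation estimators) without the heavy upstream infrastructure:
SNP-to-gene aggregation, LD-score regression, and eQTL calling are
consumed as inputs, not re-implemented.

## The statistics at the core

**Competitive enrichment.** For gene-level association Z-scores the model
is

    z_g = α + β·1[g ∈ S] + γᵀ c_g + ε_g

where `c_g` holds gene length, SNP density, inverse minor allele count and
their logs. The one-sided test of β > 0 asks whether member genes are more
associated than background genes; restricting the background to a control
superset (e.g. all protein-coding genes, or all tissue-expressed genes)
keeps the test competitive. Constraint conditioning replaces the indicator
with its residual on [1, LOEUF, log LOEUF].

**Enrichment-count null.** For a catalog of trait-associated genes, the
statistic `N_enrich` counts traits in which a target set has odds ratio
above 1 (nominal enrichment). Its null distribution comes from redrawing
same-size gene sets uniformly from the universe; the one-sided empirical
p-value `Pr(N_null ≤ N_obs)` asks whether the target is enriched in
*fewer* traits than a random set.

**Tissue specificity.** With `x̂_i = x_i / max_i x_i`,
`τ = Σ_i (1 − x̂_i) / (n − 1)` ranges from 0 (uniform expression) to 1
(single tissue); one representative tissue per correlated class is used.

**mtDNA association.** Haploid variants pass call-rate (≥ 0.95 per array
type), carrier-count (≥ 20), and expected-case (≥ 20) QC, then are tested
by linear regression — or Firth-penalized logistic regression for binary
traits, whose Jeffreys-prior penalty keeps estimates finite under the
complete separation that array-specific variants produce. Significance
uses a Bonferroni threshold over all tested phenotype-variant pairs.

**Latent trait correlations.** Binary traits are modelled as dichotomized
standard normals: tetrachoric (binary-binary) and biserial
(binary-continuous) estimators recover the latent correlation via the
two-step method; traits are ordered by their loading on the first
eigenvector of the absolute correlation matrix.

## Worked example

```python
import numpy as np
from orgenrich.simulate import SimConfig, gen_gene_table, gen_gene_stats
from orgenrich.genesets import GeneSet
from orgenrich.competitive import geneset_regression

cfg = SimConfig(seed=1, n_genes=18_000, planted_set_size=1523, enrichment_delta=0.3)
genes = gen_gene_table(cfg)
rng = np.random.default_rng(1)
target = GeneSet("planted", frozenset(rng.choice(genes["gene"], 1523, replace=False)))
stats = gen_gene_stats(cfg, list(target.members), genes)
cov = genes.set_index("gene")[["length", "snp_density", "inv_mac"]]
res = geneset_regression(stats, target, cov)
print(f"beta={res.beta:.3f} se={res.se:.3f} p={res.p_one_sided:.3g}")
```

prints

```
beta=0.347 se=0.027 p=3.63e-38
```

i.e. the planted standardized shift of 0.3 in the 1523-gene set is
recovered (β̂ = 0.35 ± 0.027) and the one-sided competitive test is
decisive. The same pipeline run with `enrichment_delta=0` gives p-values
uniform on (0, 1) — the calibration checks in `tests/test_acceptance.py`
verify this, along with the QC rules, the Firth estimator, and the
analytic thresholds (0.05/486 ≈ 1.03e-4 for the correlation analyses;
0.05/4337 ≈ 1.15e-5 for the mtDNA scan).

The same steps are scriptable from the shell:

```bash
orgenrich simulate stats --seed 1 --out data/
orgenrich enrich-run data/gene_stats.tsv data/planted.gmt data/cov.tsv
orgenrich correlate-cutoff --n-genetic 24 --n-phenotypic 21
```

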