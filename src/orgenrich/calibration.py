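"""Calibration, oracle-agreement, and parameter-recovery experiments.

These experiments validate the statistical machinery end to end on
synthetic cohorts with planted structure: analytic thresholds, exactness
of the Fisher and least-squares layers against independent references,
type-I calibration of the empirical enrichment-count null and the
competitive regression, and recovery of planted enrichment, latent
correlation, and mtDNA effects. Problem sizes are chosen to keep each
experiment at desk scale (seconds to a few minutes) while leaving Monte
Carlo error well inside the tolerances being checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import catalog as catalog_mod
from .competitive import geneset_regression, subsample_power
from .correlation import tetrachoric_corr
from .genesets import GeneSet
from .mtdna import _firth_penalized_loglik, firth_logistic, linear_assoc, mtdna_threshold, run_mtdna_gwas
from .simulate import SimConfig, gen_gene_stats, gen_gene_table, gen_mt_data, gen_phenotypes, gen_trait_catalog

__all__ = [
    "fisher_enumeration_max_diff",
    "regression_oracle_max_diff",
    "firth_grid_oracle_diff",
    "empirical_null_type1",
    "competitive_type1",
    "mtdna_null_median_chisq",
    "planted_enrichment_power",
    "power_by_size",
    "tetrachoric_recovery_rate",
    "mtdna_planted_detection",
    "random_set_decile_proportion",
]


# ---------------------------------------------------------------- oracles

def fisher_enumeration_max_diff(max_margin: int = 12) -> float:
    """Largest |p_ours - p_reference| over all 2x2 tables with margins <= max_margin.

    The in-package two-sided p sums hypergeometric point probabilities; the
    reference is scipy's independently implemented exact test.
    """
    worst = 0.0
    for row1 in range(max_margin + 1):
        for row2 in range(max_margin + 1):
            n = row1 + row2
            if n == 0:
                continue
            for col1 in range(max(0, n - max_margin), min(max_margin, n) + 1):
                for a in range(max(0, col1 - row2), min(row1, col1) + 1):
                    b, c, d = row1 - a, col1 - a, row2 - (col1 - a)
                    ours = catalog_mod.fisher_two_sided(a, b, c, d)
                    ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
                    worst = max(worst, abs(ours - min(ref, 1.0)))
    return worst


def regression_oracle_max_diff(seed: int = 0, n_designs: int = 50) -> float:
    """Worst coefficient/se deviation of the OLS layers from normal equations.

    Random small competitive designs are solved both through
    :func:`geneset_regression` and by explicit normal equations.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(14, 60))
        genes = [f"g{i:02d}" for i in range(n)]
        member = np.zeros(n)
        member[: n // 2] = 1.0
        cov = pd.DataFrame(
            {"length": rng.lognormal(2, 0.5, n), "snp_density": rng.lognormal(0, 0.3, n),
             "inv_mac": rng.uniform(0.001, 0.5, n)},
            index=pd.Index(genes, name="gene"))
        z = 0.5 * member + rng.standard_normal(n)
        stats_df = pd.DataFrame({"gene": genes, "trait": "t", "z": z})
        res = geneset_regression(stats_df, GeneSet("s", frozenset(np.array(genes)[member == 1])), cov)
        raw = cov.to_numpy()
        X = np.column_stack([np.ones(n), member, raw, np.log(raw)])
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        resid = z - X @ beta
        sigma2 = resid @ resid / (n - X.shape[1])
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        worst = max(worst, abs(res.beta - beta[1]), abs(res.se - se[1]))
    return worst


def firth_grid_oracle_diff(seed: int = 0) -> float:
    """|beta_Newton - beta_grid| for Firth logistic on an 8-observation dataset."""
    g = pd.Series([0, 0, 1, 0, 1, 1, 0, 1.0], index=[f"s{i}" for i in range(8)])
    y = pd.Series([0, 1, 0, 0, 1, 1, 0, 1.0], index=g.index)
    rec = firth_logistic(y, g, None)
    X = np.column_stack([np.ones(8), g.to_numpy()])
    yv = y.to_numpy()
    center, width = np.zeros(2), 6.0
    for _ in range(6):
        b0 = np.linspace(center[0] - width, center[0] + width, 41)
        b1 = np.linspace(center[1] - width, center[1] + width, 41)
        best, best_ll = None, -np.inf
        for x0 in b0:
            for x1 in b1:
                ll = _firth_penalized_loglik(np.array([x0, x1]), X, yv)
                if ll > best_ll:
                    best, best_ll = (x0, x1), ll
        center, width = np.array(best), width / 8
    return abs(rec.beta - center[1])


# ------------------------------------------------------------- calibration

def empirical_null_type1(
    seed: int = 0,
    n_targets: int = 500,
    n_null: int = 2000,
    n_genes: int = 4000,
    n_traits: int = 100,
    target_size: int = 300,
) -> float:
    """Pr(emp_p <= 0.05) for uniformly random target sets.

    The enrichment count is integer-valued over the tested traits, so many
    traits are simulated to keep its null distribution smooth enough for a
    tail probability to be meaningful. Because the random targets are drawn
    from the same distribution as the null samples, a single shared null of
    ``n_null`` draws is valid for every target.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_traits=n_traits)
    genes = gen_gene_table(cfg)
    universe = genes["gene"].tolist()
    cat = gen_trait_catalog(cfg, [], 1.0, genes, mean_assoc=150)
    trait_sets = catalog_mod.trait_gene_sets(cat)
    rng = np.random.default_rng(seed + 1)
    counts = np.array([
        catalog_mod.enrichment_count(
            trait_sets, frozenset(rng.choice(universe, target_size, replace=False)), universe)
        for _ in range(n_null + n_targets)
    ])
    null, targets = counts[:n_null], counts[n_null:]
    emp_p = np.array([(1.0 + (null <= t).sum()) / (1.0 + n_null) for t in targets])
    return float((emp_p <= 0.05).mean())


def competitive_type1(
    seed: int = 0,
    n_reps: int = 500,
    n_genes: int = 18_000,
    set_size: int = 1523,
    alpha: float = 0.05,
) -> float:
    """Type-I rate of the one-sided competitive regression under no enrichment."""
    cfg0 = SimConfig(seed=seed, n_genes=n_genes, enrichment_delta=0.0)
    genes = gen_gene_table(cfg0)
    cov = genes.set_index("gene")[["length", "snp_density", "inv_mac"]]
    rng = np.random.default_rng(seed + 1)
    target = GeneSet("null_set", frozenset(rng.choice(genes["gene"], set_size, replace=False)))
    hits = 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed + 10_000 + rep, n_genes=n_genes, enrichment_delta=0.0)
        stats_df = gen_gene_stats(cfg, list(target.members), genes)
        hits += geneset_regression(stats_df, target, cov).p_one_sided <= alpha
    return hits / n_reps


def mtdna_null_median_chisq(
    seed: int = 0,
    n_reps: int = 5,
    n_variants: int = 213,
    n_samples: int = 4000,
) -> float:
    """Median Wald chi-square across null mtDNA scans (theory: 0.455)."""
    chis = []
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed + 20_000 + rep, n_genes=50, n_samples=n_samples, mt_effect=0.0)
        geno, batch, pheno = gen_mt_data(cfg, n_variants=n_variants)
        res = run_mtdna_gwas(geno, batch, pheno, "y_cont")
        chis.extend((res["beta"] / res["se"]) ** 2)
    return float(np.median(chis))


# ---------------------------------------------------------------- recovery

def planted_enrichment_power(
    seed: int = 0,
    n_reps: int = 100,
    n_genes: int = 18_000,
    set_size: int = 1523,
    delta: float = 0.3,
    q_threshold: float = 0.1,
) -> float:
    """Fraction of replicates detecting a planted shift at q < 0.1.

    A single gene-set is tested per replicate, so the BH q-value equals the
    one-sided p.
    """
    cfg0 = SimConfig(seed=seed, n_genes=n_genes)
    genes = gen_gene_table(cfg0)
    cov = genes.set_index("gene")[["length", "snp_density", "inv_mac"]]
    rng = np.random.default_rng(seed + 1)
    target = GeneSet("planted", frozenset(rng.choice(genes["gene"], set_size, replace=False)))
    hits = 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed + 30_000 + rep, n_genes=n_genes, enrichment_delta=delta)
        stats_df = gen_gene_stats(cfg, list(target.members), genes)
        hits += geneset_regression(stats_df, target, cov).p_one_sided < q_threshold
    return hits / n_reps


def power_by_size(
    seed: int = 0,
    sizes=(350, 800, 1105, 1523),
    n_trials: int = 100,
    n_genes: int = 18_000,
    delta: float = 0.3,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Subsampling power curve over the standard gene-set sizes."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, enrichment_delta=delta)
    genes = gen_gene_table(cfg)
    cov = genes.set_index("gene")[["length", "snp_density", "inv_mac"]]
    rng = np.random.default_rng(seed + 1)
    source = GeneSet("source", frozenset(rng.choice(genes["gene"], max(sizes), replace=False)))
    stats_df = gen_gene_stats(cfg, list(source.members), genes)
    return subsample_power(stats_df, source, cov, sizes=sizes, n_trials=n_trials,
                           alpha=alpha, seed=seed + 2)


def tetrachoric_recovery_rate(
    seed: int = 0,
    rhos=(-0.6, 0.0, 0.3, 0.8),
    n_reps: int = 25,
    n_samples: int = 50_000,
    tol: float = 0.05,
) -> tuple[float, float]:
    """(fraction of estimates within tol of truth, worst absolute error)."""
    ok, total, worst = 0, 0, 0.0
    for i, rho in enumerate(rhos):
        corr = np.array([[1.0, rho], [rho, 1.0]])
        for rep in range(n_reps):
            cfg = SimConfig(seed=seed + 40_000 + 100 * i + rep, n_genes=50, n_traits=2,
                            n_samples=n_samples, latent_corr=corr)
            vals, _ = gen_phenotypes(cfg, binary_traits=["trait_1", "trait_2"])
            est, _, _ = tetrachoric_corr(vals["trait_1"].to_numpy(), vals["trait_2"].to_numpy())
            err = abs(est - rho)
            ok += err < tol
            total += 1
            worst = max(worst, err)
    return ok / total, worst


def _sized_mt_effect(n_samples: int, n_variants: int, power: float = 0.9,
                     min_carriers: int = 20) -> float:
    """Per-allele effect giving the stated power at the scan's Bonferroni
    threshold even for the rarest QC-passing variant (worst case)."""
    thr = mtdna_threshold(n_variants)
    z_alpha = sps.norm.isf(thr / 2.0)
    z_power = sps.norm.ppf(power)
    return float((z_alpha + z_power) / np.sqrt(min_carriers * (1.0 - min_carriers / n_samples)))


def mtdna_planted_detection(
    seed: int = 0,
    n_reps: int = 100,
    n_variants: int = 213,
    n_samples: int = 4000,
) -> dict:
    """Detection rate of a planted mtDNA effect at the Bonferroni threshold,
    plus the false-exceedance rate among non-planted replicate-variants."""
    effect = _sized_mt_effect(n_samples, n_variants)
    detected, false_hits, variant_tests = 0, 0, 0
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed + 50_000 + rep, n_genes=50, n_samples=n_samples)
        geno, batch, pheno = gen_mt_data(cfg, n_variants=n_variants, mt_effect=effect)
        planted = geno.columns[n_variants // 2]
        res = run_mtdna_gwas(geno, batch, pheno, "y_cont")
        thr = mtdna_threshold(len(res))
        res = res.set_index("variant")
        if planted in res.index and res.loc[planted, "p"] < thr:
            detected += 1
        others = res.drop(index=planted, errors="ignore")
        false_hits += int((others["p"] < thr).sum())
        variant_tests += len(others)
    return {
        "detection_rate": detected / n_reps,
        "false_rate": false_hits / max(variant_tests, 1),
        "effect": effect,
    }


def random_set_decile_proportion(seed: int = 0, n_sets: int = 200,
                                 n_genes: int = 4000, set_size: int = 200) -> float:
    """Mean lowest-LOEUF-decile proportion of uniformly random gene-sets."""
    from .constraint import decile_proportion

    cfg = SimConfig(seed=seed, n_genes=n_genes)
    genes = gen_gene_table(cfg)
    table = genes[["gene", "loeuf"]]
    rng = np.random.default_rng(seed + 1)
    props = [
        decile_proportion(frozenset(rng.choice(genes["gene"], set_size, replace=False)), table)["proportion"]
        for _ in range(n_sets)
    ]
    return float(np.mean(props))
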