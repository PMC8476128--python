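"""Seeded generators for every input table of the pipeline.

Each generator plants a known ground truth — set memberships, enrichment
shifts of gene-level Z statistics, per-allele mtDNA effects, latent-normal
trait correlations, compartment-shifted constraint distributions — so that
every downstream stage can be tested for parameter recovery. All generators
are pure functions of a :class:`SimConfig`: the same configuration (seed
included) reproduces byte-identical outputs.

Defaults emulate the regime of the real resources the tables stand in for:
an ~18,000-gene protein-coding universe, 24 age-related traits, 49 tissues
with correlated subtypes grouped into classes, haploid mtDNA genotypes on
two array batches, and a 0-5 integer localization-evidence scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, UnknownGeneError, UnknownVariantError

__all__ = [
    "SimConfig",
    "gen_gene_table",
    "gen_localization",
    "gen_gene_stats",
    "gen_trait_catalog",
    "gen_expression",
    "gen_mt_data",
    "gen_phenotypes",
    "gen_loeuf",
    "gen_eqtl_landscape",
]

# distinct substreams so generators are independent yet reproducible
_STREAMS = {
    "gene_table": 11,
    "localization": 23,
    "gene_stats": 37,
    "trait_catalog": 41,
    "expression": 53,
    "mt_data": 67,
    "phenotypes": 79,
    "loeuf": 89,
    "eqtl": 97,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    The defaults are the conditions of the analyses this package supports:
    18,000 protein-coding genes (the regime for the 350-1523-gene sets used
    in the power analysis), 24 age-related traits, 49 tissues, a planted set
    of 1523 genes with a standardized mean Z shift of 0.3.
    """

    seed: int = 0
    n_genes: int = 18_000
    n_traits: int = 24
    n_tissues: int = 49
    n_samples: int = 5_000
    planted_set_size: int = 1523
    enrichment_delta: float = 0.3
    mt_effect: float = 0.0
    latent_corr: np.ndarray | None = None
    case_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise InvalidConfigError(f"n_genes must be >= 10, got {self.n_genes}")
        for name in ("n_traits", "n_tissues", "n_samples", "planted_set_size"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise InvalidConfigError("case_fraction must lie in (0, 1)")
        if self.latent_corr is not None:
            r = np.asarray(self.latent_corr, dtype=float)
            if r.ndim != 2 or r.shape[0] != r.shape[1]:
                raise InvalidConfigError("latent_corr must be square")
            if not np.allclose(r, r.T, atol=1e-12):
                raise InvalidConfigError("latent_corr must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-12):
                raise InvalidConfigError("latent_corr must have unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise InvalidConfigError("latent_corr must be positive semi-definite")
            object.__setattr__(self, "latent_corr", r)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


def gen_gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Simulate the gene universe with per-gene regression covariates.

    Columns: ``gene`` (unique id), ``length`` (bp, log-normal), ``snp_density``
    (SNPs per kb, positive), ``inv_mac`` (inverse minor allele count in
    (0, 1]), ``loeuf`` (constraint in (0, 2]), ``phylostratum`` (1-19).
    """
    rng = cfg.rng("gene_table")
    n = cfg.n_genes
    width = max(6, len(str(n)))
    genes = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    length = rng.lognormal(mean=np.log(2.0e4), sigma=0.9, size=n)
    snp_density = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    inv_mac = 1.0 / rng.integers(1, 5001, size=n).astype(float)
    loeuf = np.clip(2.0 * rng.beta(2.0, 3.0, size=n), 1e-3, 2.0)
    phylostratum = rng.integers(1, 20, size=n)
    return pd.DataFrame(
        {
            "gene": genes,
            "length": length,
            "snp_density": snp_density,
            "inv_mac": inv_mac,
            "loeuf": loeuf,
            "phylostratum": phylostratum,
        }
    )


def gen_localization(
    cfg: SimConfig,
    compartments: Sequence[str],
    planted: Mapping[str, Sequence[str]],
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate gene x compartment localization evidence scores.

    Planted members receive integer scores in {3, 4, 5} for their compartment;
    all other (gene, compartment) pairs score in {0, 1, 2}, so the score > 2
    filter recovers exactly the planted memberships.
    """
    if genes is None:
        genes = gen_gene_table(cfg)
    universe = set(genes["gene"])
    for comp, members in planted.items():
        if comp not in compartments:
            raise InvalidConfigError(f"planted compartment {comp!r} not in compartment list")
        unknown = set(members) - universe
        if unknown:
            raise UnknownGeneError(f"planted genes not in universe: {sorted(unknown)[:5]}")
    rng = cfg.rng("localization")
    gene_arr = genes["gene"].to_numpy()
    frames = []
    for comp in compartments:
        score = rng.integers(0, 3, size=len(gene_arr))
        frames.append(pd.DataFrame({"gene": gene_arr, "compartment": comp, "score": score}))
    df = pd.concat(frames, ignore_index=True)
    df = df.set_index(["gene", "compartment"])
    for comp, members in planted.items():
        idx = [(g, comp) for g in members]
        df.loc[idx, "score"] = rng.integers(3, 6, size=len(idx))
    return df.reset_index()


def gen_gene_stats(
    cfg: SimConfig,
    target_set: Sequence[str],
    genes: pd.DataFrame | None = None,
    trait: str = "trait_1",
    length_slope: float = 0.0,
) -> pd.DataFrame:
    """Simulate gene-level association Z statistics with a planted set shift.

    Non-members draw Z from N(0, 1); members from N(enrichment_delta, 1).
    ``length_slope`` adds a linear leakage of Z onto centred log gene length.
    ``p`` is the upper-tail normal probability of Z.
    """
    if genes is None:
        genes = gen_gene_table(cfg)
    universe = set(genes["gene"])
    unknown = set(target_set) - universe
    if unknown:
        raise UnknownGeneError(f"target genes not in universe: {sorted(unknown)[:5]}")
    rng = cfg.rng("gene_stats")
    member = genes["gene"].isin(set(target_set)).to_numpy()
    z = rng.standard_normal(cfg.n_genes) + cfg.enrichment_delta * member
    if length_slope != 0.0:
        loglen = np.log(genes["length"].to_numpy())
        z = z + length_slope * (loglen - loglen.mean())
    p = stats.norm.sf(z)
    return pd.DataFrame({"gene": genes["gene"], "trait": trait, "z": z, "p": np.clip(p, 1e-300, 1.0)})


def gen_trait_catalog(
    cfg: SimConfig,
    target_set: Sequence[str],
    odds_multiplier: Mapping[str, float] | float = 1.0,
    genes: pd.DataFrame | None = None,
    mean_assoc: int = 150,
) -> pd.DataFrame:
    """Simulate a trait -> associated-gene catalog with planted in-set odds.

    For each trait, genes enter the associated list independently; in-set
    genes have their inclusion odds multiplied by the trait's multiplier.
    Every association carries an association p-value < 5e-8.
    """
    if genes is None:
        genes = gen_gene_table(cfg)
    universe = set(genes["gene"])
    unknown = set(target_set) - universe
    if unknown:
        raise UnknownGeneError(f"target genes not in universe: {sorted(unknown)[:5]}")
    traits = [f"trait_{i + 1}" for i in range(cfg.n_traits)]
    if isinstance(odds_multiplier, Mapping):
        mult = {t: float(odds_multiplier.get(t, 1.0)) for t in traits}
    else:
        mult = {t: float(odds_multiplier) for t in traits}
    if any(m <= 0 for m in mult.values()):
        raise InvalidConfigError("odds_multiplier must be > 0")
    rng = cfg.rng("trait_catalog")
    member = genes["gene"].isin(set(target_set)).to_numpy()
    gene_arr = genes["gene"].to_numpy()
    rows = []
    for t in traits:
        n_assoc = int(rng.integers(max(31, mean_assoc // 2), mean_assoc * 2))
        p0 = n_assoc / cfg.n_genes
        odds0 = p0 / (1.0 - p0)
        odds1 = odds0 * mult[t]
        p1 = odds1 / (1.0 + odds1)
        prob = np.where(member, p1, p0)
        hit = rng.random(cfg.n_genes) < prob
        chosen = gene_arr[hit]
        pvals = rng.uniform(1e-30, 5e-8, size=chosen.size)
        rows.append(pd.DataFrame({"trait": t, "gene": chosen, "assoc_p": pvals}))
    return pd.concat(rows, ignore_index=True)


def _tissue_layout(n_tissues: int) -> pd.Series:
    """Map tissues to classes; the first classes carry correlated subtypes."""
    multi = [("class_brain", 3), ("class_heart", 2)]
    names, classes = [], []
    used = 0
    for cname, k in multi:
        k = min(k, n_tissues - used)
        for j in range(k):
            names.append(f"{cname[6:]}_{j + 1}")
            classes.append(cname)
            used += 1
        if used >= n_tissues:
            break
    i = 1
    while used < n_tissues:
        names.append(f"tissue_{i}")
        classes.append(f"class_tissue_{i}")
        used += 1
        i += 1
    return pd.Series(classes, index=pd.Index(names, name="tissue"), name="tissue_class")


def gen_expression(
    cfg: SimConfig,
    specific_fraction: float = 0.3,
    genes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a gene x tissue median-TPM matrix with correlated subtypes.

    A ``specific_fraction`` of genes concentrate expression in one tissue
    class (tau near 1); the remainder are near-uniform (tau near 0). Tissues
    within a class share the specific genes' high expression, emulating
    correlated tissue subtypes. Returns (wide TPM frame indexed by gene,
    tissue -> class map).
    """
    if not 0.0 <= specific_fraction <= 1.0:
        raise InvalidConfigError("specific_fraction must lie in [0, 1]")
    if genes is None:
        genes = gen_gene_table(cfg)
    rng = cfg.rng("expression")
    layout = _tissue_layout(cfg.n_tissues)
    tissues = list(layout.index)
    classes = layout.to_numpy()
    uniq_classes = list(dict.fromkeys(classes))
    n_g, n_t = cfg.n_genes, cfg.n_tissues
    base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=n_g)
    noise = rng.uniform(0.8, 1.2, size=(n_g, n_t))
    tpm = base[:, None] * noise
    n_spec = int(round(specific_fraction * n_g))
    spec_idx = rng.choice(n_g, size=n_spec, replace=False)
    home_class = rng.choice(len(uniq_classes), size=n_spec)
    class_of = np.array([uniq_classes.index(c) for c in classes])
    for i, gi in enumerate(spec_idx):
        in_home = class_of == home_class[i]
        tpm[gi, ~in_home] *= 0.002
    df = pd.DataFrame(tpm, index=pd.Index(genes["gene"], name="gene"), columns=tissues)
    return df, layout


def gen_mt_data(
    cfg: SimConfig,
    n_variants: int = 213,
    planted_variant: str | None = None,
    mt_effect: float | None = None,
    missing_rate: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate haploid mtDNA genotypes with batches plus a phenotype table.

    Alternate-carrier counts follow a log-uniform spectrum between 20 and
    0.1 * n_samples. Samples split over two array batches with batch-specific
    missing-completely-at-random call rates. The continuous phenotype is a
    linear predictor over 20 synthetic nuclear PCs, sex and age, plus
    ``mt_effect`` x planted genotype and unit-variance noise; the binary
    phenotype dichotomizes the continuous liability at ``case_fraction``.

    Returns (genotype frame samples x variants with NaN for missing,
    array-batch series, phenotype/covariate frame).
    """
    if mt_effect is None:
        mt_effect = cfg.mt_effect
    rng = cfg.rng("mt_data")
    n = cfg.n_samples
    positions = np.sort(rng.choice(np.arange(1, 16570), size=n_variants, replace=False))
    variants = [f"MT{p}" for p in positions]
    if planted_variant is None:
        planted_variant = variants[n_variants // 2]
    if planted_variant not in variants:
        raise UnknownVariantError(f"planted variant {planted_variant!r} not simulated")
    lo, hi = np.log(20.0), np.log(max(21.0, 0.1 * n))
    carriers = np.exp(rng.uniform(lo, hi, size=n_variants)).astype(int)
    geno = np.zeros((n, n_variants))
    for j, m in enumerate(carriers):
        idx = rng.choice(n, size=min(m, n), replace=False)
        geno[idx, j] = 1.0
    batch = pd.Series(
        np.where(rng.random(n) < 0.5, "axiom", "bileve"),
        index=pd.Index([f"S{i:06d}" for i in range(1, n + 1)], name="sample"),
        name="array_batch",
    )
    samples = batch.index
    pcs = rng.standard_normal((n, 20))
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(40.0, 70.0, size=n)
    gamma_pc = rng.normal(0.0, 0.05, size=20)
    age_c = (age - age.mean()) / age.std()
    lin = pcs @ gamma_pc + 0.1 * sex + 0.1 * age_c
    gj = geno[:, variants.index(planted_variant)]
    y = lin + mt_effect * gj + rng.standard_normal(n)
    thresh = np.quantile(y, 1.0 - cfg.case_fraction)
    y_bin = (y > thresh).astype(float)
    pheno = pd.DataFrame(
        {f"pc{k + 1}": pcs[:, k] for k in range(20)}, index=samples
    )
    pheno["sex"] = sex
    pheno["age"] = age
    pheno["y_cont"] = y
    pheno["y_bin"] = y_bin
    rates = {"axiom": missing_rate, "bileve": min(0.5, 2.0 * missing_rate)}
    obs = geno.copy()
    for b, rate in rates.items():
        mask_b = (batch == b).to_numpy()
        miss = rng.random((mask_b.sum(), n_variants)) < rate
        sub = obs[mask_b]
        sub[miss] = np.nan
        obs[mask_b] = sub
    geno_df = pd.DataFrame(obs, index=samples, columns=variants)
    return geno_df, batch, pheno


def gen_phenotypes(
    cfg: SimConfig,
    binary_traits: Sequence[str] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate sample x trait values under a latent multivariate normal.

    Traits are drawn from MVN(0, latent_corr); traits named in
    ``binary_traits`` are dichotomized at their stated liability thresholds
    (default 0). Returns (value frame, trait -> {continuous, binary} map).
    """
    k = cfg.n_traits
    corr = cfg.latent_corr if cfg.latent_corr is not None else np.eye(k)
    if corr.shape[0] != k:
        raise InvalidConfigError("latent_corr dimension must equal n_traits")
    traits = [f"trait_{i + 1}" for i in range(k)]
    rng = cfg.rng("phenotypes")
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    latent = rng.standard_normal((cfg.n_samples, k)) @ root.T
    df = pd.DataFrame(latent, columns=traits)
    df.index = pd.Index([f"S{i:06d}" for i in range(1, cfg.n_samples + 1)], name="sample")
    types = {t: "continuous" for t in traits}
    for t in binary_traits or []:
        if t not in types:
            raise InvalidConfigError(f"unknown binary trait {t!r}")
        cut = (thresholds or {}).get(t, 0.0)
        df[t] = (df[t] > cut).astype(float)
        types[t] = "binary"
    return df, types


def gen_loeuf(
    cfg: SimConfig,
    compartment_shifts: Mapping[str, float],
    memberships: Mapping[str, Sequence[str]],
    genes: pd.DataFrame | None = None,
) -> pd.Series:
    """Shift per-compartment LOEUF distributions by stated amounts.

    Returns a replacement LOEUF column (positive values) for the gene table;
    genes in several shifted compartments accumulate their shifts.
    """
    if genes is None:
        genes = gen_gene_table(cfg)
    loeuf = genes["loeuf"].to_numpy().copy()
    gene_pos = {g: i for i, g in enumerate(genes["gene"])}
    for comp, shift in compartment_shifts.items():
        members = memberships.get(comp, ())
        unknown = [g for g in members if g not in gene_pos]
        if unknown:
            raise UnknownGeneError(f"genes not in universe: {unknown[:5]}")
        idx = [gene_pos[g] for g in members]
        loeuf[idx] = loeuf[idx] + shift
    loeuf = np.clip(loeuf, 1e-3, None)
    return pd.Series(loeuf, index=genes["gene"].to_numpy(), name="loeuf")


def gen_eqtl_landscape(
    cfg: SimConfig,
    organelle: Sequence[str],
    effect: float,
    genes: pd.DataFrame | None = None,
    n_rep_tissues: int = 40,
) -> pd.DataFrame:
    """Simulate a per-gene cis-eQTL landscape with a planted organelle effect.

    ``n_eqtl`` counts are Poisson around a linear predictor in the number of
    expressing tissues, tau, and ``effect`` x organelle membership, truncated
    to [0, n_rep_tissues]. Companion columns ``n_express`` and ``tau`` carry
    the covariates the landscape regression adjusts for.
    """
    if genes is None:
        genes = gen_gene_table(cfg)
    rng = cfg.rng("eqtl")
    n = cfg.n_genes
    member = genes["gene"].isin(set(organelle)).to_numpy().astype(float)
    n_express = rng.integers(1, n_rep_tissues + 1, size=n).astype(float)
    tau = rng.beta(2.0, 2.0, size=n)
    mu = 2.0 + 0.5 * n_express - 3.0 * tau + effect * member
    lam = np.clip(mu, 0.05, None)
    n_eqtl = np.minimum(rng.poisson(lam), n_rep_tissues).astype(float)
    return pd.DataFrame(
        {
            "gene": genes["gene"],
            "n_eqtl": n_eqtl,
            "n_express": n_express,
            "tau": tau,
            "organelle": member,
        }
    )
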