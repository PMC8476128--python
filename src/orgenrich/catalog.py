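"""GWAS-catalog-style gene-set screen.

For each trait, genes mapped from genome-wide-significant associations form
a trait-associated gene set; a target gene-set (e.g. the mitochondrial
proteome) is tested for enrichment or depletion against the genome
background with two-sided Fisher's exact tests, BH-corrected across traits.

The headline statistic is the enrichment count N_enrich: the number of
traits in which the target shows a *nominal* enrichment (odds ratio above
1, significant or not). Its null distribution is built empirically by
redrawing same-size gene samples uniformly from the protein-coding
universe; the one-sided empirical p-value asks whether the target is
nominally enriched in *fewer* traits than a random set of equal size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError, InvalidRecordError
from .genesets import GeneSet

__all__ = [
    "trait_gene_sets",
    "fisher_two_sided",
    "fisher_screen",
    "EnrichCount",
    "enrichment_count",
    "enrichment_count_null",
]


def trait_gene_sets(
    catalog: pd.DataFrame,
    p_threshold: float = 5e-8,
    min_genes: int = 30,
) -> dict[str, frozenset[str]]:
    """Build trait -> associated-gene sets from an association catalog.

    Keeps genes with any association at ``assoc_p < p_threshold`` (deduplicated
    per trait) and drops traits with ``<= min_genes`` associated genes.
    """
    required = {"trait", "gene", "assoc_p"}
    missing = required - set(catalog.columns)
    if missing:
        raise InvalidRecordError(f"catalog missing columns: {sorted(missing)}")
    if (catalog["assoc_p"] <= 0).any() or (catalog["assoc_p"] > 1).any():
        raise InvalidRecordError("assoc_p must lie in (0, 1]")
    hits = catalog[catalog["assoc_p"] < p_threshold]
    out: dict[str, frozenset[str]] = {}
    for trait, sub in hits.groupby("trait"):
        genes = frozenset(sub["gene"])
        if len(genes) > min_genes:
            out[str(trait)] = genes
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Classical convention: the sum of hypergeometric point probabilities not
    exceeding the observed table's probability (with a 1e-7 relative slack
    for floating-point ties).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def _table(target: frozenset[str], trait_genes: frozenset[str], universe_size: int) -> tuple[int, int, int, int]:
    a = len(target & trait_genes)
    b = len(target) - a
    c = len(trait_genes) - a
    d = universe_size - a - b - c
    return a, b, c, d


def fisher_screen(
    trait_sets: dict[str, frozenset[str]],
    target: GeneSet | frozenset[str],
    universe: list[str] | frozenset[str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-trait Fisher enrichment/depletion screen of a target gene-set.

    Returns one row per tested trait with the 2x2 table cells, sample odds
    ratio (no continuity correction), two-sided p, BH q across traits, and a
    verdict in {enriched, depleted, null} by odds-ratio direction at q < fdr.
    """
    members = frozenset(target.members if isinstance(target, GeneSet) else target)
    uni = frozenset(universe)
    if not members <= uni:
        raise InvalidRecordError("target set must be a subset of the universe")
    rows = []
    for trait in sorted(trait_sets):
        genes = frozenset(trait_sets[trait]) & uni
        if not genes:
            warnings.warn(f"trait {trait!r} has an empty gene set; skipped", stacklevel=2)
            continue
        a, b, c, d = _table(members, genes, len(uni))
        degenerate = (a + b) in (0, len(uni)) or (a + c) in (0, len(uni))
        p = 1.0 if degenerate else fisher_two_sided(a, b, c, d)
        if b * c > 0:
            orat = (a * d) / (b * c)
        elif a * d > 0:
            orat = np.inf
        else:
            orat = np.nan
        rows.append({"trait": trait, "a": a, "b": b, "c": c, "d": d, "odds_ratio": orat, "p": p})
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    _, q, _, _ = multipletests(res["p"], method="fdr_bh")
    res["q"] = q
    verdict = np.where(
        (res["q"] < fdr) & (res["odds_ratio"] > 1), "enriched",
        np.where((res["q"] < fdr) & (res["odds_ratio"] < 1), "depleted", "null"),
    )
    res["verdict"] = verdict
    return res


@dataclass(frozen=True)
class EnrichCount:
    """Observed enrichment count, its empirical null, and the one-sided p."""

    n_enrich: int
    null_counts: np.ndarray
    emp_p: float


def enrichment_count(
    trait_sets: dict[str, frozenset[str]],
    target: GeneSet | frozenset[str],
    universe: list[str],
    nominal: str = "or",
) -> int:
    """Number of traits in which the target is nominally enriched (OR > 1)."""
    members = frozenset(target.members if isinstance(target, GeneSet) else target)
    universe = list(universe)
    pos = {g: i for i, g in enumerate(universe)}
    trait_masks = np.zeros((len(trait_sets), len(universe)), dtype=float)
    for i, t in enumerate(sorted(trait_sets)):
        trait_masks[i, [pos[g] for g in trait_sets[t] if g in pos]] = 1.0
    mask = np.zeros(len(universe))
    mask[[pos[g] for g in members]] = 1.0
    return _count_nominal_enrich(mask, trait_masks, trait_masks.sum(axis=1),
                                 len(universe), nominal, len(members))


def _count_nominal_enrich(
    member_mask: np.ndarray,
    trait_masks: np.ndarray,
    trait_sizes: np.ndarray,
    universe_size: int,
    nominal: str,
    set_size: int,
) -> int:
    a = trait_masks @ member_mask  # in-set & trait-associated, per trait
    b = set_size - a
    c = trait_sizes - a
    d = universe_size - a - b - c
    enriched = a * d > b * c  # sample odds ratio > 1, ties excluded
    if nominal == "p<0.05":
        ps = np.array([fisher_two_sided(int(ai), int(bi), int(ci), int(di))
                       for ai, bi, ci, di in zip(a, b, c, d)])
        enriched &= ps < 0.05
    return int(enriched.sum())


def enrichment_count_null(
    trait_sets: dict[str, frozenset[str]],
    target: GeneSet | frozenset[str],
    universe: list[str],
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    nominal: str = "or",
    add_one: bool = True,
) -> EnrichCount:
    """Empirical null for the enrichment count of a target gene-set.

    ``n_enrich`` is computed for the target and for ``n_samples`` uniform
    same-size samples of the universe drawn without replacement. The
    one-sided empirical p-value Pr(N_null <= N_observed) uses the add-one
    estimator (1 + #{null <= observed}) / (1 + n_samples) by default.
    """
    if n_samples < 1:
        raise InvalidConfigError("n_samples must be >= 1")
    members = frozenset(target.members if isinstance(target, GeneSet) else target)
    universe = list(universe)
    if len(members) > len(universe):
        raise InvalidConfigError("target larger than universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(universe)}
    n_uni = len(universe)
    traits = sorted(trait_sets)
    trait_masks = np.zeros((len(traits), n_uni), dtype=float)
    for i, t in enumerate(traits):
        idx = [pos[g] for g in trait_sets[t] if g in pos]
        trait_masks[i, idx] = 1.0
    trait_sizes = trait_masks.sum(axis=1)
    size = len(members)
    mask = np.zeros(n_uni)
    mask[[pos[g] for g in members]] = 1.0
    observed = _count_nominal_enrich(mask, trait_masks, trait_sizes, n_uni, nominal, size)
    null_counts = np.empty(n_samples, dtype=int)
    sample_mask = np.zeros(n_uni)
    for s in range(n_samples):
        sample_mask[:] = 0.0
        sample_mask[rng.choice(n_uni, size=size, replace=False)] = 1.0
        null_counts[s] = _count_nominal_enrich(sample_mask, trait_masks, trait_sizes, n_uni, nominal, size)
    hits = int((null_counts <= observed).sum())
    if add_one:
        emp_p = (1.0 + hits) / (1.0 + n_samples)
    else:
        emp_p = hits / n_samples
    return EnrichCount(n_enrich=observed, null_counts=null_counts, emp_p=float(emp_p))
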