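"""LOEUF-based constraint summaries per gene-set.

LOEUF (loss-of-function observed/expected upper bound fraction) measures
purifying selection against heterozygous protein-truncating variants;
lower values mean stronger constraint. Gene-sets are summarized by the
proportion of their members falling in the lowest LOEUF decile of the full
gene table (with a Wilson interval) and by their mean LOEUF with a
percentile-bootstrap confidence interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidConfigError, InvalidRecordError
from .genesets import GeneSet

__all__ = ["decile_boundaries", "decile_proportion", "distribution_summary"]


def _validate_table(table: pd.DataFrame) -> pd.Series:
    if not {"gene", "loeuf"} <= set(table.columns):
        raise InvalidRecordError("constraint table needs columns gene, loeuf")
    if table["gene"].duplicated().any():
        raise InvalidRecordError("constraint table has duplicate genes")
    if (table["loeuf"] <= 0).any():
        raise InvalidRecordError("LOEUF values must be positive")
    return table.set_index("gene")["loeuf"]


def decile_boundaries(table: pd.DataFrame) -> np.ndarray:
    """The 10%..90% LOEUF quantiles of the full gene table (lower empirical
    quantile, i.e. type-1), defining the decile partition."""
    loeuf = np.sort(_validate_table(table).to_numpy())
    n = loeuf.size
    # lower empirical (type-1) quantile: the ceil(q*n)-th order statistic,
    # which partitions the table into deciles of near-equal size
    idx = np.ceil(np.arange(1, 10) / 10.0 * n).astype(int) - 1
    return loeuf[idx]


def decile_proportion(gene_set: GeneSet | frozenset[str], table: pd.DataFrame) -> dict:
    """Proportion of a gene-set in the lowest LOEUF decile, with Wilson 95% CI.

    Deciles are defined over all genes in the table; membership in the
    lowest decile uses LOEUF <= the first boundary.
    """
    loeuf = _validate_table(table)
    members = frozenset(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    in_table = [g for g in members if g in loeuf.index]
    if not in_table:
        raise InvalidConfigError("gene set has no overlap with the constraint table")
    cut = decile_boundaries(table)[0]
    hits = int((loeuf.loc[in_table] <= cut).sum())
    n = len(in_table)
    lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
    return {"proportion": hits / n, "ci_low": float(lo), "ci_high": float(hi), "n": n}


def distribution_summary(
    gene_set: GeneSet | frozenset[str],
    table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Set-restricted mean LOEUF with a seeded percentile-bootstrap 95% CI.

    Sets with fewer than two overlapping genes yield a point estimate only.
    """
    loeuf = _validate_table(table)
    members = frozenset(gene_set.members if isinstance(gene_set, GeneSet) else gene_set)
    vals = loeuf.loc[[g for g in sorted(members) if g in loeuf.index]].to_numpy()
    if vals.size == 0:
        raise InvalidConfigError("gene set has no overlap with the constraint table")
    mean = float(vals.mean())
    if vals.size < 2:
        return {"mean": mean, "ci_low": None, "ci_high": None, "n": int(vals.size)}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boots = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"mean": mean, "ci_low": float(lo), "ci_high": float(hi), "n": int(vals.size)}
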