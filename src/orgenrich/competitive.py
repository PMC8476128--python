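"""Competitive gene-set enrichment by gene-level regression.

Gene association Z statistics are regressed on a set-membership indicator
plus confounder covariates — gene length, variant density (SNPs per kb),
inverse minor allele count, and the log of each — with a one-sided test of
the membership coefficient (enrichment only). The analysis is competitive:
it asks whether member genes are *more* associated than the background
genes, where the background can be restricted to a control superset (e.g.
all protein-coding genes, or all tissue-expressed genes).

Constraint conditioning residualizes LOEUF and log LOEUF out of the
membership indicator before the main fit, so that enrichment mediated
purely through constraint is attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateDesignError, InvalidConfigError, InvalidRecordError
from .genesets import GeneSet

__all__ = [
    "EnrichResult",
    "geneset_regression",
    "condition_on_constraint",
    "bh_threshold",
    "subsample_power",
]

DEFAULT_COVARIATES = ("length", "snp_density", "inv_mac")


@dataclass(frozen=True)
class EnrichResult:
    """One-sided competitive enrichment result for a (set, trait) pair."""

    set_name: str
    trait: str
    beta: float
    se: float
    p_one_sided: float
    n_genes: int
    n_members: int
    q: float | None = None
    n_dropped: int = 0


def _covariate_matrix(cov: pd.DataFrame, names=DEFAULT_COVARIATES) -> np.ndarray:
    missing = set(names) - set(cov.columns)
    if missing:
        raise InvalidRecordError(f"covariate table missing columns: {sorted(missing)}")
    raw = cov[list(names)].to_numpy(dtype=float)
    if (raw <= 0).any():
        raise InvalidRecordError("covariates must be positive to admit log transforms")
    return np.column_stack([raw, np.log(raw)])


def _ols_onesided(y: np.ndarray, X: np.ndarray, coef_idx: int, labels: list[str]):
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        bad = [labels[j] for j in range(k)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise DegenerateDesignError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tval = beta[coef_idx] / se[coef_idx]
    p_one = float(stats.t.sf(tval, dof))
    return float(beta[coef_idx]), float(se[coef_idx]), p_one, n


def geneset_regression(
    stats_df: pd.DataFrame,
    gene_set: GeneSet,
    covariates: pd.DataFrame,
    control_superset: GeneSet | None = None,
    superset_mode: str = "restrict",
    membership: np.ndarray | None = None,
) -> EnrichResult:
    """OLS of gene Z on set membership plus confounder covariates.

    ``stats_df`` needs columns ``gene``, ``trait``, ``z``; ``covariates`` is
    indexed by gene with positive columns ``length``, ``snp_density``,
    ``inv_mac`` (their logs are added internally). With a ``control_superset``
    the analysis is restricted to the superset's genes (``superset_mode=
    'restrict'``, the competitive background) or the superset enters as an
    indicator covariate (``'covariate'``). The reported p-value is the
    upper-tail t probability of the membership coefficient.

    ``membership`` optionally overrides the indicator (used internally by
    constraint conditioning).
    """
    df = stats_df.merge(covariates, left_on="gene", right_index=True, how="inner")
    if control_superset is not None and superset_mode == "restrict":
        df = df[df["gene"].isin(control_superset.members)]
    df = df.reset_index(drop=True)
    if len(df) < 4:
        raise DegenerateDesignError("too few analyzed genes")
    if membership is None:
        member = df["gene"].isin(gene_set.members).to_numpy(dtype=float)
    else:
        member = np.asarray(membership, dtype=float)
        if member.shape[0] != len(df):
            raise InvalidConfigError("membership override length mismatch")
    if np.all(member == member[0]):
        raise DegenerateDesignError("membership indicator is constant on the analyzed genes")
    n_members = int(df["gene"].isin(gene_set.members).sum())
    cols = [np.ones(len(df)), member, _covariate_matrix(df)]
    labels = ["intercept", "membership", *DEFAULT_COVARIATES,
              *[f"log_{c}" for c in DEFAULT_COVARIATES]]
    if control_superset is not None and superset_mode == "covariate":
        sup = df["gene"].isin(control_superset.members).to_numpy(dtype=float)
        cols.append(sup[:, None])
        labels.append("control_superset")
    X = np.column_stack([np.asarray(c).reshape(len(df), -1) for c in cols])
    y = df["z"].to_numpy(dtype=float)
    beta, se, p_one, n = _ols_onesided(y, X, 1, labels)
    trait = str(df["trait"].iloc[0]) if "trait" in df else ""
    return EnrichResult(gene_set.name, trait, beta, se, p_one, n, n_members)


def condition_on_constraint(
    stats_df: pd.DataFrame,
    gene_set: GeneSet,
    covariates: pd.DataFrame,
    loeuf: pd.Series,
    control_superset: GeneSet | None = None,
    superset_mode: str = "restrict",
) -> EnrichResult:
    """Competitive regression with constraint residualized out of membership.

    Genes with missing or non-positive LOEUF are dropped (count reported in
    the result). The membership indicator is replaced by its OLS residual on
    [intercept, LOEUF, log LOEUF]; the main regression then proceeds with
    the default covariates.
    """
    lo = loeuf.reindex(stats_df["gene"])
    keep = lo.notna().to_numpy() & (lo.to_numpy(dtype=float) > 0)
    n_dropped = int((~keep).sum())
    df = stats_df.loc[keep].reset_index(drop=True)
    lo = lo[keep].to_numpy(dtype=float)
    df = df.merge(covariates, left_on="gene", right_index=True, how="inner")
    if control_superset is not None and superset_mode == "restrict":
        mask = df["gene"].isin(control_superset.members).to_numpy()
        df, lo = df[mask].reset_index(drop=True), lo[mask]
    member = df["gene"].isin(gene_set.members).to_numpy(dtype=float)
    if np.all(member == member[0]):
        raise DegenerateDesignError("membership indicator is constant on the analyzed genes")
    Z = np.column_stack([np.ones(len(df)), lo, np.log(lo)])
    coef, _, _, _ = np.linalg.lstsq(Z, member, rcond=None)
    member_resid = member - Z @ coef
    stats_cols = [c for c in ("gene", "trait", "z", "p") if c in df.columns]
    res = geneset_regression(df[stats_cols], gene_set, covariates, membership=member_resid)
    return EnrichResult(res.set_name, res.trait, res.beta, res.se, res.p_one_sided,
                        res.n_genes, res.n_members, res.q, n_dropped)


def bh_threshold(pvals, fdr: float = 0.1) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values and significance verdicts.

    Returns a frame with columns ``p``, ``q``, ``significant`` (q < fdr),
    aligned with the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return pd.DataFrame(columns=["p", "q", "significant"])
    if (p <= 0).any() or (p > 1).any():
        raise InvalidRecordError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"p": p, "q": q, "significant": q < fdr})


def subsample_power(
    stats_df: pd.DataFrame,
    source_set: GeneSet,
    covariates: pd.DataFrame,
    sizes=(350, 800, 1105, 1523),
    n_trials: int = 200,
    alpha: float = 0.05,
    p_threshold: float | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Empirical power over random subsamples of a source gene-set.

    For each size, ``n_trials`` uniform subsamples of ``source_set`` are
    tested with :func:`geneset_regression`; power is the fraction of trials
    with one-sided p at or below the significance rule (``p_threshold`` if
    given — e.g. a BH threshold from a full analysis batch — else nominal
    ``alpha``). Wilson 95% intervals accompany each estimate.
    """
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    members = sorted(source_set.members)
    for size in sizes:
        if size > len(members):
            raise InvalidConfigError(f"subsample size {size} exceeds source set ({len(members)})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cut = p_threshold if p_threshold is not None else alpha
    rows = []
    for size in sizes:
        hits = 0
        for _ in range(n_trials):
            sub = rng.choice(members, size=size, replace=False)
            res = geneset_regression(stats_df, GeneSet(f"{source_set.name}_sub{size}", frozenset(sub)), covariates)
            hits += res.p_one_sided <= cut
        lo, hi = proportion_confint(hits, n_trials, alpha=0.05, method="wilson")
        rows.append({"size": size, "power": hits / n_trials, "ci_low": lo, "ci_high": hi,
                     "n_trials": n_trials})
    return pd.DataFrame(rows)
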