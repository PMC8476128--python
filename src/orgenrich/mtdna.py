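"""mtDNA-wide association: QC and regression models.

Variants are haploid (calls in {0, 1, missing}) and genotyped on two array
types. QC drops list-excluded variants, any variant with a heterozygous
call, variants with within-array-type call rate below 0.95 or fewer than
20 alternate-genotype carriers, samples with within-array-type call rate
below 0.95, and (for binary traits) phenotype-variant pairs whose expected
case count among carriers falls below 20. Continuous traits use ordinary
linear regression; binary traits use Firth-penalized logistic regression,
which keeps estimates finite under the complete separation that
array-specific rare variants produce. Covariates follow the standard
formula: 20 nuclear PCs, sex, age, age^2, sex*age, sex*age^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import InvalidConfigError, InvalidRecordError

__all__ = [
    "AssocRecord",
    "build_covariates",
    "variant_qc",
    "sample_qc",
    "pair_qc",
    "linear_assoc",
    "firth_logistic",
    "mtdna_threshold",
    "run_mtdna_gwas",
]


@dataclass(frozen=True)
class AssocRecord:
    variant: str
    trait: str
    beta: float
    se: float
    p: float
    model: str
    n_used: int
    converged: bool = True


def build_covariates(pheno: pd.DataFrame, n_pcs: int = 20, include_array: pd.Series | None = None) -> pd.DataFrame:
    """Assemble the association covariate matrix.

    Expects ``pc1..pc<n_pcs>``, ``sex`` and ``age`` columns; derives age^2,
    sex*age and sex*age^2. ``include_array`` optionally appends an array-type
    indicator (linear models only; logistic fits omit it by default because
    array-specific variants separate completely on it).
    """
    cols = [f"pc{i + 1}" for i in range(n_pcs)] + ["sex", "age"]
    missing = set(cols) - set(pheno.columns)
    if missing:
        raise InvalidRecordError(f"phenotype table missing covariates: {sorted(missing)}")
    cov = pheno[cols].copy()
    cov["age2"] = cov["age"] ** 2
    cov["sex_age"] = cov["sex"] * cov["age"]
    cov["sex_age2"] = cov["sex"] * cov["age"] ** 2
    if include_array is not None:
        codes = pd.Categorical(include_array.reindex(cov.index)).codes.astype(float)
        cov["array"] = codes
    return cov


def _batch_call_rates(geno: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Per-variant call rate within each array type (NaN if untyped there)."""
    rates = {}
    for b, idx in batch.groupby(batch).groups.items():
        sub = geno.loc[idx]
        typed = sub.notna().sum(axis=0)
        rates[b] = np.where(typed > 0, typed / len(sub), np.nan)
    return pd.DataFrame(rates, index=geno.columns)


def variant_qc(
    geno: pd.DataFrame,
    batch: pd.Series,
    exclusion_list=(),
    call_rate_min: float = 0.95,
    min_carriers: int = 20,
) -> tuple[list[str], pd.DataFrame]:
    """Variant-level QC; returns (kept variants, per-variant QC log).

    A variant absent from one array type is judged on its own array's call
    rate only. The carrier minimum counts alternate-genotype individuals
    across all retained samples (strictly fewer than ``min_carriers`` drops
    the variant).
    """
    exclusion = set(exclusion_list)
    unknown = exclusion - set(geno.columns)
    if unknown:
        warnings.warn(f"exclusion list names unknown variants: {sorted(unknown)[:5]}", stacklevel=2)
    vals = geno.to_numpy(dtype=float)
    het = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
    has_het = pd.Series(het.any(axis=0), index=geno.columns)
    rates = _batch_call_rates(geno, batch)
    low_rate = (rates < call_rate_min).any(axis=1)
    carriers = (geno == 1).sum(axis=0)
    log_rows = []
    kept = []
    for v in geno.columns:
        reason = None
        if v in exclusion:
            reason = "exclusion_list"
        elif has_het[v]:
            reason = "heterozygous_calls"
        elif low_rate[v]:
            reason = "call_rate"
        elif carriers[v] < min_carriers:
            reason = "min_carriers"
        if reason is None:
            kept.append(v)
        log_rows.append({"variant": v, "kept": reason is None, "reason": reason,
                         "carriers": int(carriers[v])})
    return kept, pd.DataFrame(log_rows)


def sample_qc(geno: pd.DataFrame, batch: pd.Series, call_rate_min: float = 0.95) -> list[str]:
    """Drop samples with within-array-type variant call rate below threshold.

    Per array type, a sample's call rate is measured over the variants typed
    on that array (variants with at least one call in the batch).
    """
    kept = []
    for b, idx in batch.groupby(batch).groups.items():
        sub = geno.loc[idx]
        typed = sub.columns[sub.notna().any(axis=0)]
        if len(typed) == 0:
            continue
        rate = sub[typed].notna().mean(axis=1)
        kept.extend(rate.index[rate >= call_rate_min])
    return sorted(kept)


def pair_qc(
    n_carriers: int,
    case_status: pd.Series | None,
    min_expected_cases: int = 20,
) -> bool:
    """Keep a phenotype-variant pair if its expected carrier case count is adequate.

    Expected case carriers = n_carriers * (n_cases / n_total). Continuous
    traits (``case_status=None``) are always kept.
    """
    if case_status is None:
        return True
    case_status = case_status.dropna()
    if len(case_status) == 0:
        return False
    expected = n_carriers * case_status.mean()
    return bool(expected >= min_expected_cases)


def linear_assoc(
    pheno: pd.Series,
    geno: pd.Series,
    cov: pd.DataFrame,
    variant: str = "",
    trait: str = "",
) -> AssocRecord | None:
    """Per-variant linear regression with intercept and covariates.

    Samples with a missing genotype are dropped for that variant only.
    Returns None (caller logs the skip) when the genotype is constant after
    missingness.
    """
    df = pd.concat([pheno.rename("y"), geno.rename("g"), cov], axis=1).dropna()
    g = df["g"].to_numpy(dtype=float)
    if g.size == 0 or np.all(g == g[0]):
        return None
    X = np.column_stack([np.ones(len(df)), g, df.drop(columns=["y", "g"]).to_numpy(dtype=float)])
    n, k = X.shape
    if n <= k + 1:
        raise InvalidConfigError("too few samples for the covariate formula")
    y = df["y"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    tval = beta[1] / se[1]
    p = float(2.0 * stats.t.sf(abs(tval), dof))
    return AssocRecord(variant, trait, float(beta[1]), float(se[1]), max(p, 5e-324), "linear", n)


def _firth_penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    p = expit(eta)
    eps = 1e-12
    ll = float(y @ np.log(p + eps) + (1 - y) @ np.log(1 - p + eps))
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    pheno: pd.Series,
    geno: pd.Series,
    cov: pd.DataFrame | None,
    variant: str = "",
    trait: str = "",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> AssocRecord | None:
    """Firth-penalized logistic regression (Jeffreys-prior penalty).

    Maximizes l(beta) + 0.5 * log det I(beta) by Newton iteration with
    step-halving on the penalized likelihood; converges when the largest
    modified-score component drops below ``tol``. Wald standard errors come
    from the penalized information at the optimum, so estimates stay finite
    even under complete separation. Returns None when the genotype is
    constant or only one phenotype class is present.
    """
    pieces = [pheno.rename("y"), geno.rename("g")]
    if cov is not None:
        pieces.append(cov)
    df = pd.concat(pieces, axis=1).dropna()
    y = df["y"].to_numpy(dtype=float)
    g = df["g"].to_numpy(dtype=float)
    if g.size == 0 or np.all(g == g[0]) or len(np.unique(y)) < 2:
        return None
    C = df.drop(columns=["y", "g"]).to_numpy(dtype=float)
    # standardize covariates for conditioning; the genotype column is left
    # as-is so its coefficient and se are on the original scale
    if C.shape[1]:
        mu, sd = C.mean(axis=0), C.std(axis=0)
        sd[sd == 0] = 1.0
        C = (C - mu) / sd
    X = np.column_stack([np.ones(len(df)), g, C])
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    ll = _firth_penalized_loglik(beta, X, y)
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * W[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        new_beta = beta + step
        new_ll = _firth_penalized_loglik(new_beta, X, y)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _firth_penalized_loglik(new_beta, X, y)
            halvings += 1
        if np.max(np.abs(step)) < 1e-10:
            # numerical plateau of the penalized likelihood
            converged = True
            beta, ll = new_beta, new_ll
            break
        beta, ll = new_beta, new_ll
    p_fit = expit(X @ beta)
    W = p_fit * (1 - p_fit)
    info = X.T @ (X * W[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta[1] / se[1]
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return AssocRecord(variant, trait, float(beta[1]), float(se[1]), max(pval, 5e-324),
                       "firth", n, converged)


def mtdna_threshold(n_pairs: int, alpha: float = 0.05) -> float:
    """Bonferroni mtDNA-wide significance threshold over all tested pairs."""
    if n_pairs < 1:
        raise InvalidConfigError("n_pairs must be >= 1")
    return alpha / n_pairs


def run_mtdna_gwas(
    geno: pd.DataFrame,
    batch: pd.Series,
    pheno: pd.DataFrame,
    trait: str,
    binary: bool = False,
    exclusion_list=(),
    call_rate_min: float = 0.95,
    min_carriers: int = 20,
    min_expected_cases: int = 20,
    n_pcs: int = 20,
    array_covariate: bool = False,
) -> pd.DataFrame:
    """Full QC + association pass for one trait; one row per tested variant."""
    kept_samples = sample_qc(geno, batch, call_rate_min)
    geno = geno.loc[kept_samples]
    batch = batch.loc[kept_samples]
    pheno = pheno.loc[kept_samples]
    kept_variants, _ = variant_qc(geno, batch, exclusion_list, call_rate_min, min_carriers)
    y = pheno[trait]
    cov = build_covariates(pheno, n_pcs=n_pcs,
                           include_array=batch if (array_covariate and not binary) else None)
    records = []
    for v in kept_variants:
        carriers = int((geno[v] == 1).sum())
        if binary and not pair_qc(carriers, y, min_expected_cases):
            continue
        if binary:
            rec = firth_logistic(y, geno[v], cov, variant=v, trait=trait)
        else:
            rec = linear_assoc(y, geno[v], cov, variant=v, trait=trait)
        if rec is not None:
            records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records])
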