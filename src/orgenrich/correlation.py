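"""Pairwise phenotypic correlations under a latent-normal model.

Continuous-continuous pairs use Pearson correlation. Binary traits are
modelled as dichotomized latent normals: binary-binary pairs use the
tetrachoric estimator (thresholds fixed from marginal prevalences, then
the latent correlation maximizing the 2x2 bivariate-normal likelihood —
the two-step method), and binary-continuous pairs use the biserial
estimator (point-biserial rescaled by the normal density at the
threshold). p-values come from a normal approximation on estimate/se.

The module also orders traits by their loading on the first eigenvector of
the absolute correlation matrix and computes the Bonferroni cutoff shared
across the genetic and phenotypic correlation analyses.
"""

from __future__ import annotations

import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidConfigError, InvalidRecordError

__all__ = [
    "pearson_corr",
    "tetrachoric_corr",
    "biserial_corr",
    "pairwise_correlation",
    "order_by_first_eigenvector",
    "bonferroni_cutoff",
]

_RHO_BOUND = 0.999


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf([h, k]))


def _cell_probs(h: float, k: float, rho: float) -> np.ndarray:
    """2x2 quadrant probabilities for thresholds (h, k): rows X<=h / X>h, cols Y<=k / Y>k."""
    p00 = _bvn_cdf(h, k, rho)
    p0_ = stats.norm.cdf(h)
    p_0 = stats.norm.cdf(k)
    p01 = p0_ - p00
    p10 = p_0 - p00
    p11 = 1.0 - p0_ - p_0 + p00
    return np.clip(np.array([p00, p01, p10, p11]), 1e-12, 1.0)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r with normal-approximation se and p."""
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    se = np.sqrt(max(1.0 - r * r, 1e-12) / (n - 2))
    p = float(2.0 * stats.norm.sf(abs(r) / se))
    return r, float(se), p


def tetrachoric_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-step tetrachoric correlation of two binary vectors.

    Thresholds are fixed at the inverse-normal of the marginal prevalences;
    the latent correlation maximizes the multinomial likelihood of the 2x2
    table, with se from the inverse observed information at the optimum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    counts = np.array([
        np.sum((x == 0) & (y == 0)),
        np.sum((x == 0) & (y == 1)),
        np.sum((x == 1) & (y == 0)),
        np.sum((x == 1) & (y == 1)),
    ], dtype=float)
    px, py = x.mean(), y.mean()
    if px in (0.0, 1.0) or py in (0.0, 1.0):
        raise InvalidRecordError("binary trait with a single observed class")
    h = stats.norm.ppf(1.0 - px)  # X > h has probability px
    k = stats.norm.ppf(1.0 - py)

    def negll(rho: float) -> float:
        return -float(counts @ np.log(_cell_probs(h, k, rho)))

    res = optimize.minimize_scalar(negll, bounds=(-_RHO_BOUND, _RHO_BOUND),
                                   method="bounded", options={"xatol": 1e-6})
    rho = float(res.x)
    eps = 1e-4
    d2 = (negll(min(rho + eps, _RHO_BOUND)) - 2 * negll(rho) + negll(max(rho - eps, -_RHO_BOUND))) / eps**2
    se = float(1.0 / np.sqrt(max(d2, 1e-12)))
    p = float(2.0 * stats.norm.sf(abs(rho) / se))
    return rho, se, p


def biserial_corr(binary: np.ndarray, cont: np.ndarray) -> tuple[float, float, float]:
    """Two-step biserial correlation of a binary and a continuous trait.

    The point-biserial (Pearson) correlation is corrected to the latent
    scale by sqrt(p(1-p)) / phi(threshold).
    """
    b = np.asarray(binary, dtype=float)
    c = np.asarray(cont, dtype=float)
    p1 = b.mean()
    if p1 in (0.0, 1.0):
        raise InvalidRecordError("binary trait with a single observed class")
    r_pb = float(np.corrcoef(b, c)[0, 1])
    h = stats.norm.ppf(1.0 - p1)
    factor = np.sqrt(p1 * (1.0 - p1)) / stats.norm.pdf(h)
    r = float(np.clip(r_pb * factor, -1.0, 1.0))
    n = len(b)
    se_pb = np.sqrt(max(1.0 - r_pb * r_pb, 1e-12) / (n - 2))
    se = float(factor * se_pb)
    p = float(2.0 * stats.norm.sf(abs(r) / se))
    return r, se, p


def pairwise_correlation(
    data: pd.DataFrame,
    types: dict[str, str],
    min_obs: int = 10,
) -> pd.DataFrame:
    """All pairwise trait correlations with the estimator matched to trait types.

    ``data`` is sample x trait; ``types`` maps trait -> {continuous, binary}.
    Pairs use pairwise-complete observations; pairs with fewer than
    ``min_obs`` complete observations or a single-class binary trait are
    skipped with a warning.
    """
    traits = [t for t in data.columns if t in types]
    rows = []
    for i, ta in enumerate(traits):
        for tb in traits[i + 1:]:
            sub = data[[ta, tb]].dropna()
            if len(sub) < min_obs:
                warnings.warn(f"pair ({ta}, {tb}) has <{min_obs} complete observations; skipped",
                              stacklevel=2)
                continue
            a, b = sub[ta].to_numpy(), sub[tb].to_numpy()
            kinds = (types[ta], types[tb])
            try:
                if kinds == ("continuous", "continuous"):
                    r, se, p = pearson_corr(a, b)
                    est = "pearson"
                elif kinds == ("binary", "binary"):
                    r, se, p = tetrachoric_corr(a, b)
                    est = "tetrachoric"
                else:
                    if types[ta] == "binary":
                        r, se, p = biserial_corr(a, b)
                    else:
                        r, se, p = biserial_corr(b, a)
                    est = "biserial"
            except InvalidRecordError as exc:
                warnings.warn(f"pair ({ta}, {tb}) skipped: {exc}", stacklevel=2)
                continue
            rows.append({"trait_a": ta, "trait_b": tb, "estimate": float(np.clip(r, -1, 1)),
                         "se": se, "p": p, "estimator": est})
    return pd.DataFrame(rows)


def corr_matrix(entries: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Symmetric unit-diagonal correlation matrix from long-form entries."""
    m = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in entries.iterrows():
        m.loc[row["trait_a"], row["trait_b"]] = row["estimate"]
        m.loc[row["trait_b"], row["trait_a"]] = row["estimate"]
    return m


def order_by_first_eigenvector(corr: pd.DataFrame) -> list[str]:
    """Order traits by loading on the leading eigenvector of |corr|.

    The eigenvector with the largest-magnitude eigenvalue is sign-flipped so
    its largest-magnitude loading is positive; traits sort by descending
    loading with ties broken by trait label.
    """
    m = corr.to_numpy(dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise InvalidConfigError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(np.abs(m))
    lead = vecs[:, np.argmax(np.abs(vals))]
    if lead[np.argmax(np.abs(lead))] < 0:
        lead = -lead
    order = sorted(range(len(lead)), key=lambda i: (-lead[i], corr.index[i]))
    return [corr.index[i] for i in order]


def bonferroni_cutoff(n_traits_genetic: int, n_traits_phenotypic: int, alpha: float = 0.05) -> float:
    """Shared Bonferroni p cutoff over genetic plus phenotypic correlation tests.

    threshold = alpha / (C(n_g, 2) + C(n_p, 2)); an arm with fewer than two
    traits contributes zero tests.
    """
    pairs = comb(max(n_traits_genetic, 0), 2) + comb(max(n_traits_phenotypic, 0), 2)
    if pairs < 1:
        raise InvalidConfigError("no correlation hypothesis tests to correct for")
    return alpha / pairs
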