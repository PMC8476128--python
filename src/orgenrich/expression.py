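"""Tissue specificity (tau), tissue-expressed gene-sets, and the
cross-tissue eQTL-landscape regression.

tau summarizes how concentrated a gene's expression is across tissues:
with x_i the expression in tissue i and x_hat_i = x_i / max_i x_i,
tau = sum(1 - x_hat_i) / (n - 1), ranging from 0 (uniform) to 1
(single-tissue). Correlated tissue subtypes (e.g. brain sub-regions) bias
tau and the eQTL/expression tissue counts upward, so one representative
tissue per broader class is used for those quantities.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, InvalidConfigError, InvalidRecordError
from .genesets import GeneSet

__all__ = [
    "compute_tau",
    "find_tau_threshold",
    "select_representative_tissues",
    "tissue_expressed_sets",
    "count_landscape",
    "eqtl_regression",
]


def compute_tau(expr: pd.DataFrame, min_max_tpm: float = 1.0) -> pd.Series:
    """Per-gene tau from a wide gene x tissue TPM matrix.

    Genes whose maximal cross-tissue TPM is below ``min_max_tpm`` (lowly
    expressed, including all-zero genes) receive NaN.
    """
    if expr.shape[1] < 2:
        raise InvalidConfigError("tau requires at least two tissues")
    x = expr.to_numpy(dtype=float)
    if (x < 0).any():
        raise InvalidRecordError("TPM values must be non-negative")
    mx = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = x / mx[:, None]
        tau = (1.0 - xhat).sum(axis=1) / (x.shape[1] - 1)
    tau = np.where(mx < min_max_tpm, np.nan, tau)
    return pd.Series(tau, index=expr.index, name="tau")


def find_tau_threshold(
    tau_values,
    bins: int = 50,
    smooth_window: int = 3,
    fallback: float = 0.76,
) -> float:
    """Locate the central nadir of a bimodal tau distribution.

    The histogram (``bins`` over [0, 1]) is smoothed by a moving average;
    the threshold is the midpoint of the minimum-density bin between the two
    largest modes. With no interior minimum (unimodal or degenerate input)
    the supplied fixed ``fallback`` is returned with a warning.
    """
    vals = np.asarray(pd.Series(tau_values).dropna(), dtype=float)
    if vals.size < 100:
        raise InvalidConfigError("need at least 100 tau values for threshold detection")
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(counts, kernel, mode="same")
    # local maxima of the smoothed histogram
    peaks = [i for i in range(1, bins - 1)
             if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0]
    if len(peaks) < 2:
        warnings.warn("tau histogram not bimodal; using fallback threshold", stacklevel=2)
        return float(fallback)
    # the primary mode, then the tallest peak well separated from it, so
    # histogram jitter inside one mode is not mistaken for bimodality
    min_sep = max(2, bins // 10)
    primary = max(peaks, key=lambda i: smooth[i])
    distant = [i for i in peaks if abs(i - primary) >= min_sep]
    if not distant:
        warnings.warn("tau histogram not bimodal; using fallback threshold", stacklevel=2)
        return float(fallback)
    secondary = max(distant, key=lambda i: smooth[i])
    lo, hi = sorted((primary, secondary))
    interior = np.arange(lo + 1, hi)
    dens = smooth[interior]
    flat = interior[dens == dens.min()]
    nadir = int(flat[len(flat) // 2])  # middle of a flat minimum plateau
    return float((edges[nadir] + edges[nadir + 1]) / 2.0)


def select_representative_tissues(
    expr: pd.DataFrame,
    class_map: Mapping[str, str] | pd.Series,
    chosen: Mapping[str, str] | None = None,
) -> list[str]:
    """Retain one tissue per broader tissue class.

    ``chosen`` maps class -> representative tissue; classes absent from it
    keep their single tissue (or, for multi-tissue classes, the
    lexicographically first tissue). Choosing a tissue outside its class is
    an error.
    """
    cmap = pd.Series(class_map)
    chosen = dict(chosen or {})
    for cls, tissue in chosen.items():
        if cmap.get(tissue) != cls:
            raise InvalidConfigError(f"tissue {tissue!r} is not in class {cls!r}")
    kept = []
    for cls, members in cmap.groupby(cmap).groups.items():
        tissues = sorted(t for t in members if t in expr.columns)
        if not tissues:
            continue
        kept.append(chosen.get(cls, tissues[0]))
    return sorted(kept)


def tissue_expressed_sets(
    tstats: pd.DataFrame,
    top_fraction: float = 0.1,
) -> dict[str, GeneSet]:
    """Top-fraction tissue-expressed gene-sets from a gene x tissue t-statistic matrix.

    Per tissue, the ceiling(top_fraction * n_genes) genes with the highest
    statistic form that tissue's set; ties at the cutoff break by gene
    identifier.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise InvalidConfigError("top_fraction must lie in (0, 1]")
    n = int(np.ceil(top_fraction * tstats.shape[0]))
    out = {}
    for tissue in tstats.columns:
        ranked = tstats[tissue].sort_index().sort_values(ascending=False, kind="stable")
        out[tissue] = GeneSet(f"expressed_{tissue}", frozenset(ranked.index[:n]))
    return out


def count_landscape(
    qvals: pd.DataFrame,
    expr: pd.DataFrame,
    q_threshold: float = 0.05,
    tpm_threshold: float = 5.0,
    representative: Sequence[str] | None = None,
    min_max_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene eQTL landscape: tissue counts and tau.

    ``n_eqtl`` counts tissues with cis-eGene q-value < ``q_threshold``;
    ``n_express`` counts tissues with TPM strictly above ``tpm_threshold``.
    Both counts and tau are computed over the representative tissues when a
    list is supplied, else over all tissues.
    """
    if representative is not None:
        qvals = qvals[[t for t in representative if t in qvals.columns]]
        expr = expr[[t for t in representative if t in expr.columns]]
    n_eqtl = (qvals < q_threshold).sum(axis=1)
    n_express = (expr > tpm_threshold).sum(axis=1)
    tau = compute_tau(expr, min_max_tpm=min_max_tpm)
    out = pd.DataFrame({"n_eqtl": n_eqtl, "n_express": n_express, "tau": tau})
    out.index.name = "gene"
    return out.reset_index()


def eqtl_regression(
    landscape: pd.DataFrame,
    organelle: GeneSet | frozenset[str],
    gene_length: pd.Series,
) -> dict:
    """OLS of the per-gene eQTL tissue count on organelle membership.

    Model: n_eqtl ~ organelle indicator + n_express + tau + log(length) +
    length, with intercept; genes lacking tau (low expression) are excluded
    upstream and any remaining NaN rows are dropped. Returns coefficient,
    standard error and two-sided p for the indicator.
    """
    members = frozenset(organelle.members if isinstance(organelle, GeneSet) else organelle)
    df = landscape.copy()
    df["length"] = gene_length.reindex(df["gene"]).to_numpy()
    df = df.dropna(subset=["n_eqtl", "n_express", "tau", "length"])
    member = df["gene"].isin(members).to_numpy(dtype=float)
    if member.sum() == 0:
        raise DegenerateDesignError("organelle set empty after filtering")
    if np.all(member == member[0]):
        raise DegenerateDesignError("organelle indicator constant")
    length = df["length"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(df)), member,
        df["n_express"].to_numpy(dtype=float),
        df["tau"].to_numpy(dtype=float),
        np.log(length), length,
    ])
    y = df["n_eqtl"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(df) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    exact_fit = np.sqrt(sigma2) <= 1e-10 * max(1.0, float(np.abs(y).max()))
    if exact_fit or se[1] <= 0 or not np.isfinite(se[1]):
        # exact fit (e.g. constant response): no evidence either way
        p = 1.0 if abs(beta[1]) < 1e-8 else 0.0
        return {"beta": float(beta[1]), "se": float(se[1]), "p": p, "n": int(len(df))}
    tval = beta[1] / se[1]
    p = float(2.0 * stats.t.sf(abs(tval), dof))
    return {"beta": float(beta[1]), "se": float(se[1]), "p": p, "n": int(len(df))}
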