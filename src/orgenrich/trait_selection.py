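"""Systematic prioritization of age-related traits.

Diseases are ranked from period-prevalence epidemiology: those with median
onset above a cutoff are ordered by the summed period prevalence of all age
bands at or above a minimum age, and the top k taken forward. Candidate
GWAS are then filtered on heritability evidence (SNP-heritability Z-score
strictly above a threshold).
"""

from __future__ import annotations

import pandas as pd

from .errors import InvalidRecordError

__all__ = ["rank_age_related", "heritability_filter"]


def rank_age_related(
    tbl: pd.DataFrame,
    onset_min: float = 50.0,
    age_min: float = 50.0,
    top_k: int = 30,
    band_rule: str = ">=",
) -> list[str]:
    """Rank late-onset diseases by summed late-life period prevalence.

    ``tbl`` is long-form with columns ``disease``, ``median_onset``,
    ``age_lower`` (band lower bound in years) and ``prevalence``. Diseases
    with ``median_onset > onset_min`` are scored by the sum of prevalence
    over bands whose lower bound satisfies ``band_rule`` against ``age_min``
    (default: lower bound >= age_min); the first ``top_k`` are returned with
    ties broken lexicographically by disease identifier.
    """
    if tbl.empty:
        return []
    required = {"disease", "median_onset", "age_lower", "prevalence"}
    missing = required - set(tbl.columns)
    if missing:
        raise InvalidRecordError(f"prevalence table missing columns: {sorted(missing)}")
    prev = tbl["prevalence"]
    if (prev < 0).any() or (prev > 1).any():
        raise InvalidRecordError("prevalence values must lie in [0, 1]")
    if band_rule == ">=":
        in_band = tbl["age_lower"] >= age_min
    elif band_rule == ">":
        in_band = tbl["age_lower"] > age_min
    else:
        raise InvalidRecordError(f"band_rule must be '>=' or '>', got {band_rule!r}")
    onset = tbl.groupby("disease")["median_onset"].first()
    eligible = onset[onset > onset_min].index
    scores = (
        tbl[in_band]
        .groupby("disease")["prevalence"]
        .sum()
        .reindex(eligible, fill_value=0.0)
    )
    ranked = scores.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:top_k])


def heritability_filter(records: pd.DataFrame, z_min: float = 4.0) -> pd.DataFrame:
    """Retain traits whose SNP-heritability Z-score (h2/se) exceeds ``z_min``.

    The inequality is strict, matching the inclusion rule h2/se > 4. Rows
    with non-positive standard errors are invalid.
    """
    required = {"trait", "h2", "se"}
    missing = required - set(records.columns)
    if missing:
        raise InvalidRecordError(f"heritability table missing columns: {sorted(missing)}")
    if (records["se"] <= 0).any():
        bad = records.loc[records["se"] <= 0, "trait"].tolist()
        raise InvalidRecordError(f"non-positive heritability se for traits: {bad[:5]}")
    z = records["h2"] / records["se"]
    return records[z > z_min].copy()
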