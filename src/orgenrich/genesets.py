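"""Gene-set construction from subcellular-localization evidence.

Proteome gene-sets are derived from COMPARTMENTS-style confidence scores
(integer evidence levels 0-5 per gene x compartment). A gene is assigned to
the compartment(s) achieving its maximal score among assignments with
score > 2; compartments must exceed a minimum size to be retained, and the
mitochondrion can be replaced wholesale by a curated inventory
(MitoCarta-style). The nucleus is subdivided into largely disjoint spatial
subsets, and transcription factors are partitioned by tissue specificity,
evolutionary age, and DNA-binding-domain class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, UnknownGeneError

__all__ = [
    "GeneSet",
    "assign_compartments",
    "mito_override",
    "build_nuclear_subsets",
    "partition_tfs",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers, optionally tied to a control superset."""

    name: str
    members: frozenset[str]
    control_superset: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def _validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "compartment", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise InvalidRecordError(f"localization table missing columns: {sorted(missing)}")
    if scores.duplicated(["gene", "compartment"]).any():
        raise InvalidRecordError("duplicate (gene, compartment) rows in localization table")
    vals = scores["score"].to_numpy()
    if not np.array_equal(vals, vals.astype(int)) or vals.min() < 0 or vals.max() > 5:
        raise InvalidRecordError("scores must be integers in [0, 5]")
    return scores


def assign_compartments(
    scores: pd.DataFrame,
    min_score: int = 2,
    min_size: int = 240,
    mito_list: Sequence[str] | None = None,
    mito_name: str = "mitochondrion",
) -> list[GeneSet]:
    """Derive compartment gene-sets from localization confidence scores.

    Per gene, assignments with ``score > min_score`` are kept and the gene is
    placed in every compartment achieving its maximal remaining score (ties
    yield multiple assignments). Compartments with ``<= min_size`` members are
    dropped (strictly-greater size rule). When ``mito_list`` is given, the
    mitochondrion set is replaced by that curated list before size filtering.
    """
    scores = _validate_scores(scores)
    kept = scores[scores["score"] > min_score]
    sets: dict[str, set[str]] = {}
    if not kept.empty:
        maxima = kept.groupby("gene")["score"].transform("max")
        top = kept[kept["score"] == maxima]
        for comp, sub in top.groupby("compartment"):
            sets[str(comp)] = set(sub["gene"])
    if mito_list is not None:
        known = set(scores["compartment"].unique()) | set(sets)
        if mito_name not in known:
            raise UnknownGeneError(f"unknown compartment for override: {mito_name!r}")
        sets[mito_name] = set(mito_list)
    out = [
        GeneSet(name, frozenset(members))
        for name, members in sets.items()
        if len(members) > min_size
    ]
    return sorted(out, key=lambda s: s.name)


def mito_override(sets: Iterable[GeneSet], mitocarta: Sequence[str], mito_name: str = "mitochondrion") -> list[GeneSet]:
    """Replace the mitochondrion set with a curated higher-confidence list."""
    out = []
    replaced = False
    for s in sets:
        if s.name == mito_name:
            out.append(GeneSet(mito_name, frozenset(mitocarta), s.control_superset, s.description))
            replaced = True
        else:
            out.append(s)
    if not replaced:
        out.append(GeneSet(mito_name, frozenset(mitocarta)))
    return out


def build_nuclear_subsets(
    nuclear_scores: pd.DataFrame,
    tf_list: Sequence[str],
    universe: Iterable[str] | None = None,
    min_score: int = 2,
    min_size: int = 0,
    chromosome_name: str = "chromosome",
    nucleoplasm_name: str = "nucleoplasm",
) -> list[GeneSet]:
    """Split the nuclear proteome into largely disjoint spatial subsets.

    ``nuclear_scores`` holds sub-compartment localization scores restricted to
    nucleus-localizing genes. The emitted sets are: nucleoplasm (with genes
    also assigned to another nuclear sub-compartment removed), the merged
    chromosome-and-TF category, every other scored sub-compartment (e.g.
    nucleolus, nuclear envelope), and ``other_nucleus`` for nucleus members
    assigned to none of the above. Exclusivity is applied before the size
    filter.
    """
    nucleus_members = set(nuclear_scores["gene"].unique())
    if universe is not None:
        universe = set(universe)
        dropped = [g for g in tf_list if g not in universe]
        if dropped:
            warnings.warn(f"{len(dropped)} TF genes absent from universe; skipped", stacklevel=2)
        tf_list = [g for g in tf_list if g in universe]
    raw = {s.name: set(s.members) for s in assign_compartments(nuclear_scores, min_score, min_size=0)}
    chromosome = raw.pop(chromosome_name, set())
    nucleoplasm = raw.pop(nucleoplasm_name, set())
    chromosome_tf = chromosome | set(tf_list)
    others = {name: members for name, members in raw.items()}
    other_union: set[str] = set().union(*others.values()) if others else set()
    nucleoplasm_excl = nucleoplasm - (chromosome_tf | other_union)
    assigned = nucleoplasm_excl | chromosome_tf | other_union
    other_nucleus = nucleus_members - assigned
    emitted = {
        nucleoplasm_name: nucleoplasm_excl,
        "chromosome_and_tf": chromosome_tf,
        **others,
        "other_nucleus": other_nucleus,
    }
    return [
        GeneSet(name, frozenset(members))
        for name, members in emitted.items()
        if len(members) > min_size
    ]


def partition_tfs(
    tf_list: Sequence[str],
    tau: Mapping[str, float],
    tau_threshold: float = 0.76,
    age_stratum: Mapping[str, int] | None = None,
    dbd: Mapping[str, str] | None = None,
    krab_label: str = "KRAB-ZF",
    zf_label: str = "ZF",
) -> list[GeneSet]:
    """Partition transcription factors into functional subsets.

    Emits tissue-specific (tau >= threshold) vs broadly expressed TFs, age
    terciles by phylostratum rank (stable rank over the TF list itself), and
    DNA-binding-domain groups (KRAB zinc finger / other zinc finger /
    non-zinc-finger). TFs without a tau value (filtered for low expression)
    are excluded from the tau partition but retained elsewhere.
    """
    tfs = list(dict.fromkeys(tf_list))
    out: list[GeneSet] = []

    with_tau = [g for g in tfs if g in tau and not pd.isna(tau[g])]
    specific = [g for g in with_tau if tau[g] >= tau_threshold]
    broad = [g for g in with_tau if tau[g] < tau_threshold]
    out.append(GeneSet("tf_tissue_specific", frozenset(specific)))
    out.append(GeneSet("tf_broad", frozenset(broad)))

    if age_stratum is not None:
        aged = [g for g in tfs if g in age_stratum]
        order = sorted(aged, key=lambda g: (age_stratum[g], g))  # stable rank
        n = len(order)
        bounds = [round(n / 3), round(2 * n / 3)]
        out.append(GeneSet("tf_age_tercile_1", frozenset(order[: bounds[0]])))
        out.append(GeneSet("tf_age_tercile_2", frozenset(order[bounds[0] : bounds[1]])))
        out.append(GeneSet("tf_age_tercile_3", frozenset(order[bounds[1] :])))

    if dbd is not None:
        krab = [g for g in tfs if dbd.get(g) == krab_label]
        other_zf = [g for g in tfs if g in dbd and dbd[g] != krab_label and zf_label in dbd[g]]
        non_zf = [g for g in tfs if g in dbd and zf_label not in dbd[g]]
        out.append(GeneSet("tf_krab_zf", frozenset(krab)))
        out.append(GeneSet("tf_non_krab_zf", frozenset(other_zf)))
        out.append(GeneSet("tf_non_zf", frozenset(non_zf)))

    return out


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    """Write gene-sets in GMT format (name, description, tab-separated members)."""
    with open(path, "w") as fh:
        for s in sets:
            fields = [s.name, s.description or "na", *s.sorted_members()]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> list[GeneSet]:
    """Read gene-sets from a GMT file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, desc, *members = line.split("\t")
            out.append(GeneSet(name, frozenset(members), description="" if desc == "na" else desc))
    return out
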