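"""Locus catalogue: deduplication, taxonomy tabulation, clade statistics.

Byte-identical NS1 proteins mined at distinct genomic positions are
paralogous copies of one integration lineage; they are collapsed to a
single representative before any comparative analysis. Clade-level
identity/coverage contrasts use classical one-way ANOVA with Tukey HSD
post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from eve_codiv.orfs import NS1Locus

__all__ = ["DedupReport", "CladeStats", "dedup_identical", "one_way_anova",
           "tukey_hsd", "taxonomy_table", "assign_clades", "clade_stats"]


@dataclass
class DedupReport:
    groups: list[tuple[str, list[str]]]   # (representative, all members)
    n_input: int
    n_unique: int
    n_duplicate_groups: int


@dataclass
class CladeStats:
    per_clade: pd.DataFrame               # n, mean, sd per clade and metric
    anova_f: dict[str, float]
    anova_p: dict[str, float]
    tukey: dict[str, dict[tuple[str, str], float]]


def dedup_identical(loci: list[NS1Locus]
                    ) -> tuple[DedupReport, list[NS1Locus]]:
    """Group loci by exact protein string; the representative of each
    group is the lexicographically smallest locus id."""
    by_protein: dict[str, list[NS1Locus]] = {}
    for loc in loci:
        by_protein.setdefault(loc.orf.protein, []).append(loc)
    groups = []
    unique = []
    for prot, members in by_protein.items():
        members = sorted(members, key=lambda l: l.locus_id)
        groups.append((members[0].locus_id, [m.locus_id for m in members]))
        unique.append(members[0])
    groups.sort(key=lambda g: g[0])
    unique.sort(key=lambda l: l.locus_id)
    report = DedupReport(
        groups=groups, n_input=len(loci), n_unique=len(unique),
        n_duplicate_groups=sum(1 for _, m in groups if len(m) > 1))
    return report, unique


def _check_groups(groups: dict[str, list[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} needs n >= 2")


def one_way_anova(groups: dict[str, list[float]]) -> tuple[float, float]:
    """Classical between/within mean-square F and its p-value."""
    _check_groups(groups)
    f, p = stats.f_oneway(*[np.asarray(v, float) for v in groups.values()])
    return float(f), float(p)


def tukey_hsd(groups: dict[str, list[float]]
              ) -> dict[tuple[str, str], float]:
    """Studentized-range adjusted p-value for every pair of groups."""
    _check_groups(groups)
    labels = list(groups)
    res = stats.tukey_hsd(*[np.asarray(groups[l], float) for l in labels])
    out = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            out[(a, labels[j])] = float(res.pvalue[i, j])
    return out


def taxonomy_table(loci: list[NS1Locus],
                   taxonomy: dict[str, tuple[str, str, str]]) -> pd.DataFrame:
    """Counts of loci per (order, family, genus, species) flow row."""
    rows = []
    for loc in loci:
        if loc.species not in taxonomy:
            raise KeyError(f"species {loc.species!r} has no taxonomy entry")
        order, family, genus = taxonomy[loc.species]
        rows.append((order, family, genus, loc.species))
    df = pd.DataFrame(rows, columns=["order", "family", "genus", "species"])
    return (df.value_counts().rename("n").reset_index()
            .sort_values(["order", "family", "genus", "species"])
            .reset_index(drop=True))


def assign_clades(matrix, cutoff: float = 55.0) -> dict[str, str]:
    """Single-linkage clades: connected components of the graph joining
    pairs with identity >= cutoff. Labels clade_1.. by decreasing size,
    ties by first member id."""
    labels = matrix.labels
    n = len(labels)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= cutoff:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(find(i), []).append(lab)
    ordered = sorted(comps.values(), key=lambda c: (-len(c), sorted(c)[0]))
    return {member: f"clade_{k + 1}"
            for k, comp in enumerate(ordered) for member in comp}


def clade_stats(loci: list[NS1Locus]) -> CladeStats:
    """Per-clade identity/coverage summary with ANOVA + Tukey HSD."""
    df = pd.DataFrame({
        "clade": [l.clade for l in loci],
        "identity": [l.confirm_identity for l in loci],
        "coverage": [l.confirm_coverage for l in loci],
    })
    per = (df.groupby("clade").agg(["count", "mean", "std"])
           .rename(columns={"count": "n", "std": "sd"}))
    anova_f, anova_p, tuk = {}, {}, {}
    for metric in ("identity", "coverage"):
        groups = {c: g[metric].tolist() for c, g in df.groupby("clade")}
        f, p = one_way_anova(groups)
        anova_f[metric], anova_p[metric] = f, p
        tuk[metric] = tukey_hsd(groups)
    return CladeStats(per_clade=per, anova_f=anova_f, anova_p=anova_p,
                      tukey=tuk)
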