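"""Pairwise identity matrices and ICTV Parvoviridae demarcation.

Identity is computed SDT-style: sequences are globally aligned pair by
pair (Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.2) and identity
is matches over alignment columns, with a gap against a residue counted
as a difference and dual-gap columns excluded; identity = 100·(1 − p)
for p the p-distance. The demarcation classifier applies the ICTV
thresholds for the family: same species requires >85% NS1 amino-acid
identity with >80% coverage; genus membership requires identity at or
above a configurable floor (default 35, from the published 35–40% band).
A focal sequence below 75% identity to every other member is flagged as
a candidate novel taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from eve_codiv.search import ScoringScheme

__all__ = ["IdentityMatrix", "DemarcationCall", "global_align",
           "pairwise_identity", "build_matrix", "classify_pair",
           "flag_novel", "trim_columns"]


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray            # percent identity, symmetric, diag 100
    order: list[int]              # display permutation (NJ leaf order)

    def identity(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.2f}" for v in self.values[i])
                fh.write(f"{lab}\t{row}\n")


@dataclass
class DemarcationCall:
    pair: tuple[str, str]
    level: str                    # same_species | same_genus | distinct | unresolved
    identity: float
    coverage: float


_GLOBAL_SCHEME = ScoringScheme(gap_open=-10.0, gap_extend=-0.2)


def global_align(a: str, b: str, gap_open: float = 10.0,
                 gap_extend: float = 0.2, matrix: str = "BLOSUM62"
                 ) -> tuple[str, str]:
    """Needleman–Wunsch global alignment; penalties given as positive
    costs. Returns the two gapped sequences."""
    if not a or not b:
        raise ValueError("empty input sequence")
    scheme = (_GLOBAL_SCHEME if (gap_open, gap_extend, matrix) ==
              (10.0, 0.2, "BLOSUM62")
              else ScoringScheme(matrix_name=matrix, gap_open=-gap_open,
                                 gap_extend=-gap_extend))
    aln = scheme.aligner("global").align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


def pairwise_identity(aligned_a: str, aligned_b: str,
                      ignore_gaps: bool = False) -> float:
    """Percent identity of an aligned pair.

    Default (SDT convention): matches / columns-with-at-least-one-residue;
    a gap opposite a residue is a difference, dual-gap columns are
    skipped. ``ignore_gaps=True`` restricts to dual-residue columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    matches = cols = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            continue
        if ignore_gaps and (x == "-" or y == "-"):
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        raise ValueError("no scorable columns")
    return 100.0 * matches / cols


def build_matrix(proteins: dict[str, str], min_len: int = 400,
                 ignore_gaps: bool = False) -> IdentityMatrix:
    """All-pairs identity over proteins of at least ``min_len`` residues.

    Display order comes from the leaf order of a midpoint-rooted
    neighbour-joining tree on (100 − identity) distances — layout
    plumbing only, not a phylogenetic claim.
    """
    kept = {k: v for k, v in sorted(proteins.items()) if len(v) >= min_len}
    if len(kept) < 2:
        raise ValueError("fewer than 2 sequences pass the length filter")
    labels = list(kept)
    n = len(labels)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb = global_align(kept[labels[i]], kept[labels[j]])
            vals[i, j] = vals[j, i] = pairwise_identity(ga, gb, ignore_gaps)
    order = _nj_order(labels, vals)
    return IdentityMatrix(labels=labels, values=vals, order=order)


def _nj_order(labels: list[str], vals: np.ndarray) -> list[int]:
    if len(labels) < 3:
        return list(range(len(labels)))
    from skbio import DistanceMatrix
    from skbio.tree import nj
    dist = 100.0 - vals
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    tree = nj(DistanceMatrix(dist, labels))
    try:
        tree = tree.root_at_midpoint()
    except Exception:            # zero-length corner cases keep NJ rooting
        pass
    tip_order = [t.name for t in tree.tips()]
    return [labels.index(name) for name in tip_order]


def classify_pair(identity: float, coverage: float,
                  species_id: float = 85.0, species_cov: float = 80.0,
                  genus_floor: float = 35.0) -> DemarcationCall:
    """ICTV demarcation of one pair from identity and coverage (percent)."""
    for v in (identity, coverage):
        if not 0.0 <= v <= 100.0:
            if np.isnan(v):
                return DemarcationCall(("", ""), "unresolved",
                                       identity, coverage)
            raise ValueError("identity/coverage must be in [0, 100]")
    if identity > species_id and coverage > species_cov:
        level = "same_species"
    elif identity >= genus_floor:
        level = "same_genus"
    else:
        level = "distinct"
    return DemarcationCall(("", ""), level, identity, coverage)


def flag_novel(matrix: IdentityMatrix, focal_id: str,
               cutoff: float = 75.0) -> tuple[bool, float]:
    """True if the focal sequence is below ``cutoff`` percent identity to
    every other member; also returns its maximum off-diagonal identity."""
    if focal_id not in matrix.labels:
        raise KeyError(focal_id)
    i = matrix.labels.index(focal_id)
    others = np.delete(matrix.values[i], i)
    max_id = float(others.max())
    return max_id < cutoff, max_id


def trim_columns(msa: list[str], min_consensus: float = 50.0) -> list[str]:
    """Drop alignment columns whose modal non-gap residue is carried by
    fewer than ``min_consensus`` percent of the non-gap rows."""
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment is not rectangular")
    keep = []
    for c in range(width):
        col = [row[c] for row in msa if row[c] != "-"]
        if not col:
            continue
        modal = max(col.count(x) for x in set(col))
        if 100.0 * modal / len(col) >= min_consensus:
            keep.append(c)
    return ["".join(row[c] for c in keep) for row in msa]
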