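"""Shared fixtures and independent oracles for the test suite.

The alignment oracles here are deliberately naive O(n*m) Gotoh dynamic
programs, written without reference to the package's alignment path, so
they can certify it on small inputs.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG = -10 ** 9


def gotoh_local(a: str, b: str, open_s: float = -11.0,
                ext_s: float = -1.0) -> float:
    """Exhaustive affine-gap Smith-Waterman score; a gap of length k
    costs open_s + (k-1)*ext_s."""
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), float(NEG))   # gap in b (consume a)
    Y = np.full((n + 1, m + 1), float(NEG))   # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                       Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] + open_s, X[i - 1, j] + ext_s,
                          Y[i - 1, j] + open_s)
            Y[i, j] = max(M[i, j - 1] + open_s, Y[i, j - 1] + ext_s,
                          X[i, j - 1] + open_s)
            best = max(best, M[i, j])
    return best


def gotoh_global(a: str, b: str, open_s: float = -10.0,
                 ext_s: float = -0.2) -> float:
    """Exhaustive affine-gap Needleman-Wunsch score (same gap convention)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), float(NEG))
    X = np.full((n + 1, m + 1), float(NEG))
    Y = np.full((n + 1, m + 1), float(NEG))
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_s + (i - 1) * ext_s
    for j in range(1, m + 1):
        Y[0, j] = open_s + (j - 1) * ext_s
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = s + prev
            X[i, j] = max(M[i - 1, j] + open_s, X[i - 1, j] + ext_s,
                          Y[i - 1, j] + open_s)
            Y[i, j] = max(M[i, j - 1] + open_s, Y[i, j - 1] + ext_s,
                          X[i, j - 1] + open_s)
    return max(M[n, m], X[n, m], Y[n, m])


def brute_force_orfs(contig: str, code: int, min_len: int):
    """Enumerate every ATG and its first in-frame stop on both strands;
    independent of the package's segment-scanning implementation."""
    from eve_codiv.synthetic import reverse_complement
    from Bio.Data import CodonTable
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    found = set()
    L = len(contig)
    for strand, seq in (("+", contig), ("-", reverse_complement(contig))):
        for i in range(len(seq) - 2):
            if seq[i:i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= len(seq):
                codon = seq[j:j + 3]
                if codon in stops:
                    break
                j += 3
            else:
                continue
            # 5'-most ATG rule: skip if an upstream in-frame ATG exists
            # with no intervening stop
            k = i - 3
            shadowed = False
            while k >= 0:
                c = seq[k:k + 3]
                if c in stops:
                    break
                if c == "ATG":
                    shadowed = True
                    break
                k -= 3
            if shadowed:
                continue
            nt_len = j + 3 - i
            if nt_len < min_len:
                continue
            s, e = i, j + 3
            if strand == "-":
                s, e = L - e, L - s
            found.add((s, e, strand))
    return found


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic assembly set shared across tests."""
    from eve_codiv.synthetic import SimulationConfig, simulate_dataset
    cfg = SimulationConfig(n_species=4, contigs_per_species=2,
                           contig_length=40_000, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_loci(small_dataset):
    from eve_codiv.orfs import mine_assembly
    return mine_assembly(small_dataset.contigs, small_dataset.panel,
                         species_of=small_dataset.species_of)
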