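"""Flanking-sequence extraction and GC-contrast integration evidence.

Genuine chromosomal integration leaves a viral coding region embedded in
host sequence of a different base composition. For every locus the 300 bp
up- and downstream of the ORF are extracted (following the ORF's own
orientation on minus-strand loci) and the GC content of the left flank,
coding region, and right flank are compared; a paired t-test of coding
GC against the locus's own left flank quantifies the contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from eve_codiv.synthetic import reverse_complement

__all__ = ["FlankRecord", "extract_flanks", "gc_content", "flank_stats",
           "FlankStatsResult"]


@dataclass
class FlankRecord:
    locus_id: str
    species: str
    left_seq: str
    right_seq: str
    left_len: int
    right_len: int
    gc_left: float        # NaN when the flank has no unambiguous base
    gc_ns1: float
    gc_right: float


@dataclass
class FlankStatsResult:
    region_means: dict[str, float]
    region_sds: dict[str, float]
    t_statistic: float
    p_value: float
    n_pairs: int
    per_species: pd.DataFrame
    site_map: pd.DataFrame        # locus rows: left/NS1/right lengths + GC


def gc_content(seq: str) -> float:
    """Percent G+C over unambiguous bases; NaN when none are present."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        return math.nan
    return 100.0 * gc / denom


def extract_flanks(locus, contig: str, flank_len: int = 300) -> FlankRecord:
    """Flanks around a locus; truncated at contig bounds.

    ``locus`` needs .orf (start, end, strand), .locus_id and .species
    (an NS1Locus) — or a TruthRecord, handled for convenience. Left and
    right follow the ORF orientation: for minus-strand loci the left
    (upstream) flank is the genomic right interval, reverse-complemented.
    """
    if hasattr(locus, "orf"):
        start, end, strand = locus.orf.start, locus.orf.end, locus.orf.strand
        locus_id, species = locus.locus_id, locus.species
    else:
        start, end, strand = locus.orf_start, locus.orf_end, locus.strand
        locus_id, species = f"{locus.contig_id}:{start}", locus.species
    if not (0 <= start < end <= len(contig)):
        raise ValueError("locus coordinates outside contig")
    g_left = contig[max(0, start - flank_len):start]
    g_right = contig[end:end + flank_len]
    orf_nt = contig[start:end]
    if strand == "-":
        left_seq = reverse_complement(g_right)
        right_seq = reverse_complement(g_left)
        orf_nt = reverse_complement(orf_nt)
    else:
        left_seq, right_seq = g_left, g_right
    return FlankRecord(
        locus_id=locus_id, species=species,
        left_seq=left_seq, right_seq=right_seq,
        left_len=len(left_seq), right_len=len(right_seq),
        gc_left=gc_content(left_seq), gc_ns1=gc_content(orf_nt),
        gc_right=gc_content(right_seq))


def flank_stats(records: list[FlankRecord],
                min_flank: int = 50) -> FlankStatsResult:
    """Region GC summaries and the paired left-flank-vs-coding t-test.

    Records whose left or right flank is shorter than ``min_flank`` nt
    are kept in the report tables but excluded from the paired test
    (short flanks have high-variance GC).
    """
    usable = [r for r in records
              if r.left_len >= min_flank and r.right_len >= min_flank
              and not math.isnan(r.gc_left) and not math.isnan(r.gc_ns1)]
    if len(usable) < 2:
        raise ValueError("need at least 2 complete records for the test")
    left = np.array([r.gc_left for r in usable])
    ns1 = np.array([r.gc_ns1 for r in usable])
    right = np.array([r.gc_right for r in usable])
    t, p = stats.ttest_rel(ns1, left)
    if np.isnan(t):               # zero variance of differences
        t, p = 0.0, 1.0
    means = {"left_flank": float(left.mean()), "ns1": float(ns1.mean()),
             "right_flank": float(np.nanmean(right))}
    sds = {"left_flank": float(left.std(ddof=1)),
           "ns1": float(ns1.std(ddof=1)),
           "right_flank": float(np.nanstd(right, ddof=1))}
    rows = [{"locus_id": r.locus_id, "species": r.species,
             "left_len": r.left_len, "right_len": r.right_len,
             "gc_left": r.gc_left, "gc_ns1": r.gc_ns1,
             "gc_right": r.gc_right,
             "in_test": r in usable} for r in records]
    site_map = pd.DataFrame(rows)
    per_species = (site_map.groupby("species")
                   [["gc_left", "gc_ns1", "gc_right"]].mean())
    return FlankStatsResult(region_means=means, region_sds=sds,
                            t_statistic=float(t), p_value=float(p),
                            n_pairs=len(usable), per_species=per_species,
                            site_map=site_map)
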