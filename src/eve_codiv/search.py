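"""Six-frame translated homology search of contigs against a protein panel.

Each contig is translated in all six frames (standard code by default —
the reference panel consists of standard-code viral proteins) and
locally aligned against the NS1 panel with affine-gap Smith–Waterman
(BLOSUM62, open -11 / extend -1). Significance uses the Karlin–Altschul
formula E = K·m·n·exp(-λS) with published gapped-BLOSUM62 parameters.
Hits above the e-value ceiling are dropped, overlapping hits are merged
into loci, and only the best subject per locus is retained (the
``keep_top=1`` convention of tabular translated-search tools).

An exact full-matrix search over every frame is available
(``prefilter=False``); the default shares k-mer seeds with the panel
first and only extends around seeded windows, which changes nothing on
true hits but keeps genome-scale inputs fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from eve_codiv.synthetic import reverse_complement

__all__ = ["ScoringScheme", "TranslatedHit", "FrameTranslation",
           "six_frame_translate", "local_align", "evalue", "search",
           "write_outfmt6"]


@dataclass
class ScoringScheme:
    """Protein scoring model: substitution matrix, affine gaps, and the
    Karlin–Altschul (lambda, K) pair used for e-values.

    Gap convention: a gap of length k costs ``gap_open + (k-1)*gap_extend``
    (both stored as the negative scores applied).
    """
    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        self._matrix = substitution_matrices.load(self.matrix_name)
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be given as scores <= 0")

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = mode
        a.substitution_matrix = self._matrix
        a.open_gap_score = self.gap_open
        a.extend_gap_score = self.gap_extend
        return a

    def bitscore(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2.0)


@dataclass
class TranslatedHit:
    contig_id: str
    frame: int                       # +1..+3, -1..-3
    subject_id: str
    contig_start: int                # nt, 0-based half-open, forward strand
    contig_end: int
    subject_start: int               # aa, 0-based half-open
    subject_end: int
    raw_score: float
    bitscore: float
    evalue: float
    pct_identity: float
    aln_len: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class FrameTranslation:
    """One frame's protein together with its coordinate map."""
    frame: int
    protein: str
    contig_len: int

    def nt_interval(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nt interval of aa slice [aa_start, aa_end)."""
        f = abs(self.frame) - 1
        s, e = f + 3 * aa_start, f + 3 * aa_end
        if self.frame > 0:
            return s, e
        return self.contig_len - e, self.contig_len - s


def six_frame_translate(contig: str, code: int = 1) -> list[FrameTranslation]:
    """Translate all six frames; stops as '*', ambiguity as 'X'."""
    if len(contig) < 3:
        raise ValueError("contig shorter than 3 nt")
    out = []
    rc = reverse_complement(contig)
    for strand, seq in ((1, contig), (-1, rc)):
        for f in range(3):
            n = (len(seq) - f) // 3 * 3
            prot = str(Seq(seq[f:f + n]).translate(table=code))
            out.append(FrameTranslation(strand * (f + 1), prot, len(contig)))
    return out


def local_align(query: str, subject: str,
                scheme: ScoringScheme | None = None):
    """Optimal affine-gap local alignment.

    Returns (raw_score, aligned block pairs, pct_identity,
    (q_start, q_end), (s_start, s_end)); identity is matches over
    alignment columns (gap columns included).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    scheme = scheme or ScoringScheme()
    aln = scheme.aligner("local").align(query, subject)
    if aln.score <= 0:
        return 0.0, [], 0.0, (0, 0), (0, 0)
    best = aln[0]
    qa, sa = best.aligned
    matches = sum(
        1
        for (qs, qe), (ss, _) in zip(qa, sa)
        for k in range(qe - qs)
        if query[qs + k] == subject[ss + k]
    )
    q_span = (int(qa[0][0]), int(qa[-1][1]))
    s_span = (int(sa[0][0]), int(sa[-1][1]))
    aligned = sum(qe - qs for qs, qe in qa)
    gaps = (q_span[1] - q_span[0] - aligned) + (s_span[1] - s_span[0] - aligned)
    columns = aligned + gaps
    pct = 100.0 * matches / columns if columns else 0.0
    pairs = [((int(qs), int(qe)), (int(ss), int(se)))
             for (qs, qe), (ss, se) in zip(qa, sa)]
    return float(aln.score), pairs, pct, q_span, s_span


def evalue(raw_score: float, m: int, n: int,
           scheme: ScoringScheme | None = None) -> float:
    """Karlin–Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    scheme = scheme or ScoringScheme()
    return scheme.K * m * n * math.exp(-scheme.lam * raw_score)


# ---------------------------------------------------------------------------

def _kmer_windows(protein: str, subject: str, k: int, min_seeds: int):
    """Candidate (start, end) aa windows of `protein` sharing >= min_seeds
    exact k-mers with `subject`; neighbouring seeds are pooled."""
    if len(subject) < k or len(protein) < k:
        return []
    kmers = {subject[i:i + k] for i in range(len(subject) - k + 1)}
    hits = [i for i in range(len(protein) - k + 1) if protein[i:i + k] in kmers]
    if len(hits) < min_seeds:
        return []
    margin = len(subject)
    windows: list[list[int]] = []
    for h in hits:
        if windows and h - windows[-1][1] <= 2 * margin:
            windows[-1][1] = h
            windows[-1][2] += 1
        else:
            windows.append([h, h, 1])
    return [(max(0, a - margin), min(len(protein), b + k + margin))
            for a, b, cnt in windows if cnt >= min_seeds]


def _merge_hits(hits: list[TranslatedHit], keep_top: int,
                min_frac: float = 0.5) -> list[TranslatedHit]:
    """Pool hits whose contig intervals overlap by more than ``min_frac``
    of the shorter one into a locus; keep the ``keep_top`` best per locus
    (score desc, then subject id, then start)."""
    hits = sorted(hits, key=lambda h: (h.contig_id, h.contig_start,
                                       h.contig_end, h.subject_id))
    loci: list[list[TranslatedHit]] = []
    for h in hits:
        placed = False
        for locus in loci:
            ref = locus[0]
            if ref.contig_id != h.contig_id:
                continue
            ov = min(ref.contig_end, h.contig_end) - max(ref.contig_start,
                                                         h.contig_start)
            short = min(ref.contig_end - ref.contig_start,
                        h.contig_end - h.contig_start)
            if short > 0 and ov > min_frac * short:
                locus.append(h)
                placed = True
                break
        if not placed:
            loci.append([h])
    out = []
    for locus in loci:
        locus.sort(key=lambda h: (-h.raw_score, h.subject_id, h.contig_start))
        out.extend(locus[:keep_top])
    out.sort(key=lambda h: (h.contig_id, h.contig_start, h.subject_id))
    return out


def search(assembly: dict[str, str], panel: dict[str, str],
           evalue_max: float = 1e-5, keep_top: int = 1,
           scheme: ScoringScheme | None = None, code: int = 1,
           prefilter: bool = True, k: int = 6,
           min_seeds: int = 2) -> list[TranslatedHit]:
    """Search every contig of ``assembly`` against the NS1 ``panel``.

    Returns per-locus best hits with E <= ``evalue_max``, sorted by
    (contig, start); results are independent of contig/panel input order.
    """
    if not assembly or not panel:
        raise ValueError("assembly and panel must be non-empty")
    scheme = scheme or ScoringScheme()
    db_len = sum(len(p) for p in panel.values())
    raw_hits: list[TranslatedHit] = []
    for contig_id in sorted(assembly):
        contig = assembly[contig_id]
        if len(contig) < 3:
            continue
        for ft in six_frame_translate(contig, code=code):
            m = len(ft.protein)
            if m == 0:
                continue
            for subject_id in sorted(panel):
                subject = panel[subject_id]
                if prefilter:
                    windows = _kmer_windows(ft.protein, subject, k, min_seeds)
                else:
                    windows = [(0, m)]
                # one hit per seeded window: distinct loci of the same
                # frame live in separate windows and must all surface
                for (a, b) in windows:
                    score, pairs, pct, qs, ss = local_align(
                        ft.protein[a:b], subject, scheme)
                    if score <= 0:
                        continue
                    qs = (qs[0] + a, qs[1] + a)
                    e = evalue(score, m, db_len, scheme)
                    if e > evalue_max:
                        continue
                    c0, c1 = ft.nt_interval(*qs)
                    aligned = sum(qe - q0 for (q0, qe), _ in pairs)
                    gaps = ((qs[1] - qs[0] - aligned)
                            + (ss[1] - ss[0] - aligned))
                    raw_hits.append(TranslatedHit(
                        contig_id=contig_id, frame=ft.frame,
                        subject_id=subject_id,
                        contig_start=c0, contig_end=c1,
                        subject_start=ss[0], subject_end=ss[1],
                        raw_score=score, bitscore=scheme.bitscore(score),
                        evalue=e, pct_identity=pct, aln_len=aligned + gaps))
    return _merge_hits(raw_hits, keep_top)


def write_outfmt6(hits: list[TranslatedHit], path: str | Path) -> None:
    """BLAST tabular (outfmt 6) TSV; 1-based inclusive coordinates, with
    reversed qstart/qend for minus-strand hits, as translated-search
    tools print them."""
    with open(path, "w") as fh:
        for h in hits:
            if h.frame > 0:
                q1, q2 = h.contig_start + 1, h.contig_end
            else:
                q1, q2 = h.contig_end, h.contig_start + 1
            matches = round(h.pct_identity * h.aln_len / 100.0)
            fh.write("\t".join(map(str, [
                h.contig_id, h.subject_id, f"{h.pct_identity:.2f}",
                h.aln_len, h.aln_len - matches, 0,
                q1, q2, h.subject_start + 1, h.subject_end,
                f"{h.evalue:.2e}", f"{h.bitscore:.1f}"])) + "\n")
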