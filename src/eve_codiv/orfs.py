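"""ORF location and NS1 confirmation under a configurable genetic code.

A translated-search hit only marks a candidate region; the element
itself is defined as the open reading frame containing the hit,
re-translated under the flatworm mitochondrial code (NCBI table 9:
AAA→Asn, AGA/AGG→Ser, TGA→Trp relative to the standard code) and
confirmed by alignment back to the reference panel. ORFs run from the
5'-most ATG of a stop-bounded frame segment to the stop codon, must
reach a minimum length (default 702 nt, stop included), and are
reported on both strands in forward-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from eve_codiv.search import ScoringScheme, TranslatedHit, local_align
from eve_codiv.synthetic import reverse_complement

__all__ = ["OrfRecord", "NS1Locus", "translate", "find_orfs", "assign_orf",
           "confirm", "mine_assembly"]

DEFAULT_CODE = 9          # Echinoderm/Flatworm mitochondrial
MIN_ORF_LEN = 702         # nt, stop codon included


@dataclass
class OrfRecord:
    contig_id: str
    start: int            # nt, 0-based half-open, forward strand
    end: int
    strand: str
    protein: str          # stop excluded
    code: int

    @property
    def nt_len(self) -> int:
        return self.end - self.start


@dataclass
class NS1Locus:
    """A confirmed endogenous NS1 element."""
    orf: OrfRecord
    species: str
    best_subject: str
    confirm_identity: float
    confirm_coverage: float
    locus_id: str
    clade: str = "unassigned"


def translate(nt: str, code: int = DEFAULT_CODE) -> str:
    """Codon-wise translation; stops as '*', ambiguous codons as 'X'."""
    if len(nt) < 3 or len(nt) % 3 != 0:
        raise ValueError("length must be a positive multiple of 3")
    return str(Seq(nt).translate(table=code))


def find_orfs(contig: str, code: int = DEFAULT_CODE,
              min_len: int = MIN_ORF_LEN, both_strands: bool = True
              ) -> list[OrfRecord]:
    """All qualifying ORFs of a contig, sorted by (start, strand).

    Within each frame, segments are bounded by stop codons; the 5'-most
    ATG of a segment opens the reported ORF, which must reach ``min_len``
    nt including its stop. Segments running off the contig end (no stop)
    are not reported.
    """
    if not contig:
        return []
    out: list[OrfRecord] = []
    strands = [("+", contig)]
    if both_strands:
        strands.append(("-", reverse_complement(contig)))
    L = len(contig)
    for strand, seq in strands:
        for f in range(3):
            n = (len(seq) - f) // 3 * 3
            if n < 3:
                continue
            prot = translate(seq[f:f + n], code)
            seg_start = 0
            while True:
                stop = prot.find("*", seg_start)
                if stop == -1:
                    break
                m = prot.find("M", seg_start, stop)
                if m != -1:
                    nt_len = (stop + 1 - m) * 3
                    if nt_len >= min_len:
                        s = f + 3 * m
                        e = f + 3 * (stop + 1)
                        if strand == "-":
                            s, e = L - e, L - s
                        out.append(OrfRecord(
                            contig_id="", start=s, end=e, strand=strand,
                            protein=prot[m:stop], code=code))
                seg_start = stop + 1
    out.sort(key=lambda o: (o.start, o.strand))
    return out


def assign_orf(hit: TranslatedHit, orfs: list[OrfRecord]) -> OrfRecord | None:
    """The ORF containing the hit: same strand, covering >= 80% of the
    hit interval; ties broken by longest ORF, then smallest start."""
    hlen = hit.contig_end - hit.contig_start
    if hlen <= 0:
        return None
    best = None
    for orf in orfs:
        if orf.strand != hit.strand:
            continue
        ov = min(orf.end, hit.contig_end) - max(orf.start, hit.contig_start)
        if ov >= 0.8 * hlen:
            key = (-orf.nt_len, orf.start)
            if best is None or key < best[0]:
                best = (key, orf)
    return best[1] if best else None


def confirm(protein: str, panel: dict[str, str],
            scheme: ScoringScheme | None = None
            ) -> tuple[str, float, float]:
    """Best panel match of a candidate protein.

    Returns (subject id, percent identity over alignment columns,
    percent of the subject covered by the aligned span).
    """
    if not protein:
        raise ValueError("empty protein")
    if not panel:
        raise ValueError("empty panel")
    scheme = scheme or ScoringScheme()
    best = None
    for sid in sorted(panel):
        score, pairs, pct, qs, ss = local_align(protein, panel[sid], scheme)
        cov = 100.0 * (ss[1] - ss[0]) / len(panel[sid]) if pairs else 0.0
        key = (-score, sid)
        if best is None or key < best[0]:
            best = (key, sid, pct, cov)
    return best[1], best[2], best[3]


def mine_assembly(assembly: dict[str, str], panel: dict[str, str],
                  hits: list[TranslatedHit] | None = None,
                  species_of: dict[str, str] | None = None,
                  code: int = DEFAULT_CODE, min_len: int = MIN_ORF_LEN,
                  evalue_max: float = 1e-5,
                  scheme: ScoringScheme | None = None,
                  prefilter: bool = True) -> list[NS1Locus]:
    """Search (unless hits are supplied), locate containing ORFs,
    re-translate under ``code`` and confirm against the panel.

    Hits whose contig carries no qualifying ORF around them are dropped.
    Locus ids are ``<contig id with dots as underscores>_<ordinal>``,
    ordinals assigned per contig in coordinate order.
    """
    if hits is None:
        from eve_codiv.search import search as _search
        hits = _search(assembly, panel, evalue_max=evalue_max,
                       scheme=scheme, prefilter=prefilter)
    by_contig: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    loci: list[NS1Locus] = []
    for contig_id in sorted(by_contig):
        orfs = find_orfs(assembly[contig_id], code=code, min_len=min_len)
        for o in orfs:
            o.contig_id = contig_id
        chosen: dict[tuple[int, int, str], OrfRecord] = {}
        for h in sorted(by_contig[contig_id],
                        key=lambda h: (h.contig_start, h.subject_id)):
            orf = assign_orf(h, orfs)
            if orf is None:
                continue
            chosen.setdefault((orf.start, orf.end, orf.strand), orf)
        sp = (species_of or {}).get(contig_id, "unknown")
        for i, key in enumerate(sorted(chosen), start=1):
            orf = chosen[key]
            subject, ident, cov = confirm(orf.protein, panel, scheme)
            locus_id = f"{contig_id.replace('.', '_')}_{i}"
            loci.append(NS1Locus(orf=orf, species=sp, best_subject=subject,
                                 confirm_identity=ident,
                                 confirm_coverage=cov, locus_id=locus_id))
    return loci
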