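"""Synthetic assemblies with planted NS1 loci and known ground truth.

The generator emulates the structure of the real inputs the pipeline is
designed for: multi-contig flatworm genome scaffolds carrying integrated
densovirus NS1 open reading frames with a characteristic compositional
signature — strongly AT-rich left flanks, a moderate-GC coding region
(defaults 15.52% and 41.84% GC), paralogous byte-identical copies, and
lineage divergence of the NS1 protein along a known species tree.

Everything is driven by a single integer seed through
``numpy.random.default_rng``; a fixed :class:`SimulationConfig` yields
byte-identical FASTA/TSV output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import yaml
from Bio.Data import CodonTable

__all__ = [
    "TruthRecord", "SimulationConfig", "SyntheticDataset",
    "make_scaffold", "evolve_protein", "plant_eve", "make_mosaic",
    "make_structure_pair", "protein_to_nt", "simulate_dataset",
    "reverse_complement",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# codon machinery

def _codon_map(table_id: int) -> dict[str, str]:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    m = dict(t.forward_table)
    for c in t.stop_codons:
        m[c] = "*"
    return m


def _dual_safe_codons() -> dict[str, list[str]]:
    """Codons translating identically under the standard (1) and flatworm
    mitochondrial (9) tables, neither a stop in either; keyed by residue."""
    t1, t9 = _codon_map(1), _codon_map(9)
    out: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in t9.items():
        if aa != "*" and t1.get(codon) == aa:
            out[aa].append(codon)
    return {aa: sorted(cs) for aa, cs in out.items()}

_SAFE = _dual_safe_codons()
_GC_COUNT = {c: c.count("G") + c.count("C")
             for cs in _SAFE.values() for c in cs}


def protein_to_nt(protein: str, rng, gc_target: float | None = None,
                  dual_safe: bool = True) -> str:
    """Back-translate ``protein`` into an ORF (stop codon appended).

    By default only codons that read identically under NCBI tables 1 and 9
    are used, so the planted ORF is found both by a standard-code
    translated search and by flatworm-mitochondrial-code ORF prediction.
    With ``dual_safe=False`` the ORF uses a TGA stop (table-1 stop that
    table 9 reads through as Trp) — a negative control for code handling.

    When ``gc_target`` (percent) is given, synonymous codons are swapped
    greedily until the coding-region GC is as close to the target as the
    amino-acid composition allows.
    """
    rng = _rng(rng)
    if not protein or protein[0] != "M":
        raise ValueError("ORF protein must start with Met")
    codons = []
    for aa in protein:
        choices = _SAFE.get(aa)
        if not choices:
            raise ValueError(f"unsupported residue {aa!r}")
        codons.append(choices[rng.integers(len(choices))])
    stop = "TAA" if dual_safe else "TGA"
    if gc_target is not None:
        _tune_gc(codons, stop, gc_target, rng)
    return "".join(codons) + stop


def _tune_gc(codons: list[str], stop: str, gc_target: float,
             rng: np.random.Generator) -> None:
    total_nt = 3 * (len(codons) + 1)
    want = gc_target / 100.0 * total_nt
    have = sum(_GC_COUNT[c] for c in codons) + stop.count("G") + stop.count("C")
    order = rng.permutation(len(codons))
    # two passes: big moves first, then refine
    for _ in range(2):
        for i in order:
            cur = codons[i]
            res = _SAFE_BY_CODON[cur]
            best = cur
            best_err = abs(have - want)
            for alt in _SAFE[res]:
                err = abs(have - _GC_COUNT[cur] + _GC_COUNT[alt] - want)
                if err < best_err:
                    best, best_err = alt, err
            if best != cur:
                have += _GC_COUNT[best] - _GC_COUNT[cur]
                codons[i] = best

_SAFE_BY_CODON = {c: aa for aa, cs in _SAFE.items() for c in cs}


# ---------------------------------------------------------------------------
# domain records

@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth description of one planted NS1 locus.

    Coordinates are 0-based half-open on the forward strand of the contig;
    ``protein`` is the translation of the planted ORF (stop excluded)
    under the flatworm mitochondrial code.
    """
    contig_id: str
    species: str
    orf_start: int
    orf_end: int
    strand: str
    protein: str
    left_flank_gc: float
    right_flank_gc: float
    paralog_group: int


@dataclass
class FlankSpec:
    left_gc: float = 15.52
    right_gc: float = 44.0
    flank_len: int = 300


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic assembly set.

    GC defaults follow the compositional regime reported for real
    integrations (NS1 coding regions ~41.84% GC over strongly AT-rich
    left flanks of ~15.52%); the default ORF length of 1,947 nt encodes
    648 residues plus a stop, matching the mean NS1 length the pipeline
    targets. 300 bp flanks mirror the analysis window used downstream.
    """
    n_species: int = 10
    contigs_per_species: int = 2
    contig_length: int = 100_000
    background_gc: float = 38.0
    ns1_gc: float = 41.84
    left_flank_gc: float = 15.52
    right_flank_gc: float = 44.0
    flank_len: int = 300
    orf_len: int = 1947
    loci_per_species: int = 3
    n_paralog_pairs: int = 3
    n_recombinants: int = 0
    divergence_tree: str | None = None
    subs_rate: float = 0.3
    panel_rate: float = 0.25
    subs_rate_model: str = "poisson-aa"
    seed: int = 0

    def __post_init__(self):
        for name in ("background_gc", "ns1_gc", "left_flank_gc",
                     "right_flank_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.orf_len % 3 != 0 or self.orf_len < 6:
            raise ValueError("orf_len must be a positive codon multiple")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    contigs: dict[str, str]                 # contig_id -> sequence
    species_of: dict[str, str]              # contig_id -> species
    truth: list[TruthRecord]
    panel: dict[str, str]                   # reference NS1 proteins
    tree: str                               # newick over species

    def write(self, outdir: str | Path) -> None:
        """One FASTA per species, truth TSV, panel FASTA, config YAML."""
        outdir = Path(outdir)
        genomes = outdir / "genomes"
        genomes.mkdir(parents=True, exist_ok=True)
        by_sp: dict[str, list[str]] = {}
        for cid, seq in self.contigs.items():
            by_sp.setdefault(self.species_of[cid], []).append(cid)
        for sp, cids in sorted(by_sp.items()):
            with open(genomes / f"{sp}.fasta", "w") as fh:
                for cid in cids:
                    fh.write(f">{sp}|{cid}\n")
                    seq = self.contigs[cid]
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i:i + 80] + "\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("contig\tstart\tend\tstrand\tspecies\tparalog_group"
                     "\tleft_flank_gc\tright_flank_gc\tprotein\n")
            for t in self.truth:
                fh.write(f"{t.contig_id}\t{t.orf_start}\t{t.orf_end}\t"
                         f"{t.strand}\t{t.species}\t{t.paralog_group}\t"
                         f"{t.left_flank_gc:.4f}\t{t.right_flank_gc:.4f}\t"
                         f"{t.protein}\n")
        with open(outdir / "panel.fasta", "w") as fh:
            for name, prot in sorted(self.panel.items()):
                fh.write(f">{name}\n{prot}\n")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.config), fh,
                           sort_keys=True)
        with open(outdir / "species_tree.nwk", "w") as fh:
            fh.write(self.tree + "\n")


# ---------------------------------------------------------------------------
# generator operations

def make_scaffold(length: int, gc: float, seed) -> str:
    """i.i.d. background sequence with P(G)+P(C) = gc/100, split evenly."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 100.0:
        raise ValueError("gc must be in [0, 100]")
    rng = _rng(seed)
    g = gc / 200.0
    a = (1.0 - gc / 100.0) / 2.0
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                       size=length, p=[a, g, g, a])
    return bases.tobytes().decode()


def evolve_protein(root: str, tree: str, rate: float, seed) -> dict[str, str]:
    """Evolve ``root`` along a newick tree by Poisson substitution.

    Per branch the substitution count is Poisson(branch_length * rate *
    len(root)); each substitution hits a uniform site and replaces the
    residue with a uniform different one. Returns tip label -> sequence.
    """
    if not root:
        raise ValueError("root sequence must be non-empty")
    rng = _rng(seed)
    t = dendropy.Tree.get(data=tree, schema="newick",
                          preserve_underscores=True)
    seqs: dict[int, str] = {id(t.seed_node): root}
    tips: dict[str, str] = {}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            seq = root
        else:
            parent = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            seq = mutate_protein(parent, bl * rate * len(root), rng)
        seqs[id(node)] = seq
        if node.is_leaf():
            tips[node.taxon.label] = seq
    return tips


def mutate_protein(seq: str, expected_subs: float,
                   rng: np.random.Generator) -> str:
    n = rng.poisson(expected_subs)
    if n == 0:
        return seq
    chars = list(seq)
    for _ in range(n):
        i = int(rng.integers(len(chars)))
        alts = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = alts[rng.integers(len(alts))]
    return "".join(chars)


def _validate_orf(orf_nt: str, code: int = 9) -> None:
    if len(orf_nt) % 3 != 0 or len(orf_nt) < 6:
        raise ValueError("ORF length must be a codon multiple >= 6")
    cmap = _codon_map(code)
    if orf_nt[:3] != "ATG":
        raise ValueError("ORF must start with ATG")
    if cmap[orf_nt[-3:]] != "*":
        raise ValueError("ORF must end in a stop codon of the configured code")
    for i in range(0, len(orf_nt) - 3, 3):
        if cmap[orf_nt[i:i + 3]] == "*":
            raise ValueError(f"internal stop codon at nt {i}")


def plant_eve(scaffold: str, orf_nt: str, position: int, flank_spec: FlankSpec,
              seed, species: str = "sp", contig_id: str = "contig",
              strand: str = "+", paralog_group: int = 0,
              code: int = 9) -> tuple[str, TruthRecord]:
    """Insert an ORF with regenerated compositional flanks into a scaffold.

    The flank_len nt to the left of ``position`` are regenerated at
    ``left_gc``, the ORF replaces ``[position, position+len)``, and the
    flank_len nt to the right are regenerated at ``right_gc``. For minus
    strand loci the reverse complement of the ORF is inserted and the
    up/downstream flank compositions follow the ORF's own orientation.

    The upstream flank is sanitised so that, reading in frame away from
    the start codon, no ATG precedes the first stop codon: any such ATG
    is resampled from the flank's own base composition (and in the rare
    flank with no in-frame stop at all, the outermost complete codon
    becomes TAA). Without this an accidental upstream in-frame ATG would
    silently extend the true ORF coordinates; the resampling leaves the
    flank's GC expectation essentially unchanged (< 0.05 points).
    """
    _validate_orf(orf_nt, code)
    rng = _rng(seed)
    fl = flank_spec.flank_len
    L = len(orf_nt)
    if position - fl < 0 or position + L + fl > len(scaffold):
        raise ValueError("ORF plus flanks does not fit in scaffold")
    if strand not in "+-":
        raise ValueError("strand must be + or -")

    left_gc = flank_spec.left_gc
    right_gc = flank_spec.right_gc
    up = _sanitize_upstream(make_scaffold(fl, left_gc, rng), left_gc, rng,
                            code)
    down = make_scaffold(fl, right_gc, rng)
    if strand == "+":
        left, right = up, down
        insert = orf_nt
    else:
        # ORF-upstream flank sits genomic-right, reverse-complemented
        left, right = reverse_complement(down), reverse_complement(up)
        insert = reverse_complement(orf_nt)

    contig = (scaffold[:position - fl] + left + insert + right
              + scaffold[position + L + fl:])
    from eve_codiv.orfs import translate
    protein = translate(orf_nt, code).rstrip("*")
    rec = TruthRecord(
        contig_id=contig_id, species=species,
        orf_start=position, orf_end=position + L, strand=strand,
        protein=protein,
        left_flank_gc=left_gc, right_flank_gc=right_gc,
        paralog_group=paralog_group,
    )
    return contig, rec


def _sanitize_upstream(flank: str, gc: float, rng: np.random.Generator,
                       code: int = 9) -> str:
    """Ensure no in-frame ATG precedes the first in-frame stop when
    reading upstream from the flank's 3' end (which abuts the ORF start).

    Offending ATG codons are resampled from the flank's own composition,
    so the planted start codon stays the 5'-most ATG of its stop-bounded
    segment while the flank's GC expectation is preserved.
    """
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    codons = [flank[i - 3:i] for i in range(len(flank), 2, -3)]  # 3'->5'
    for idx, codon in enumerate(codons):
        if codon in stops:
            break
        while codons[idx] == "ATG":
            codons[idx] = make_scaffold(3, gc, rng)
        if codons[idx] in stops:
            break
    else:
        if codons:
            codons[-1] = "TAA"
    out = list(flank)
    for idx, codon in enumerate(codons):
        pos = len(flank) - 3 * (idx + 1)
        out[pos:pos + 3] = codon
    return "".join(out)


def make_mosaic(parent_a: str, parent_b: str, breakpoints) -> str:
    """Alternate segments of two aligned sequences, starting with A."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal aligned lengths")
    bps = list(breakpoints)
    if bps != sorted(bps) or any(not 0 <= b <= len(parent_a) for b in bps):
        raise ValueError("breakpoints must be sorted and within range")
    out = []
    prev = 0
    src = (parent_a, parent_b)
    for i, b in enumerate(bps + [len(parent_a)]):
        out.append(src[i % 2][prev:b])
        prev = b
    return "".join(out)


def make_structure_pair(n_residues: int, perturb_sd: float,
                        rotation=(0.0, 0.0, 0.0), seed=0,
                        step: float = 3.8):
    """Two Cα coordinate sets related by a rigid motion plus noise.

    The first set is a random fixed-step (3.8 Å) walk; the second is the
    first rotated by the given Euler angles (degrees, xyz), translated,
    and perturbed with iid Gaussian noise of the given SD per axis. The
    returned true RMSD is the superposition RMSD of the noisy pair,
    computed numerically.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    from scipy.spatial.transform import Rotation
    rng = _rng(seed)
    steps = rng.normal(size=(n_residues - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    a = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps * step, axis=0)])
    R = Rotation.from_euler("xyz", rotation, degrees=True).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    b = a @ R.T + t + rng.normal(scale=perturb_sd, size=a.shape)
    from eve_codiv.structures import kabsch_rmsd
    true_rmsd = kabsch_rmsd(a, b)[0]
    return a, b, true_rmsd


def simulate_clock_tree(n_tips: int, rate_sd: float = 0.0, seed=0,
                        depth: float = 1.0):
    """Random ultrametric tree with optional per-branch rate distortion.

    Tip ages are 0; internal nodes arise at increasing ages up to
    ``depth``. Each branch length is its time duration multiplied by an
    independent lognormal rate with mean 1 and the given log-scale SD
    (``rate_sd=0`` gives a strict clock). Returns (newick, true_ages)
    where true_ages maps frozenset-of-tip-labels -> node age; under the
    clock the tree is ultrametric and branch lengths equal durations.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed)
    ages = np.sort(rng.uniform(0.05 * depth, depth, size=n_tips - 1))
    ages[-1] = depth
    clades = [(f"t{i + 1}", 0.0, frozenset([f"t{i + 1}"]))
              for i in range(n_tips)]
    true_ages: dict[frozenset, float] = {}
    mrca_pairs: dict[frozenset, tuple[str, str]] = {}

    def branch(sub_newick: str, child_age: float, parent_age: float) -> str:
        duration = parent_age - child_age
        rate = (math.exp(rng.normal(-rate_sd ** 2 / 2.0, rate_sd))
                if rate_sd > 0 else 1.0)
        return f"{sub_newick}:{duration * rate:.10f}"

    for age in ages:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        nj, aj, sj = clades.pop(j)
        ni, ai, si = clades.pop(i)
        merged = f"({branch(ni, ai, age)},{branch(nj, aj, age)})"
        tips = si | sj
        true_ages[tips] = float(age)
        mrca_pairs[tips] = (min(si), min(sj))   # true MRCA is this node
        clades.append((merged, float(age), tips))
    return clades[0][0] + ";", true_ages, mrca_pairs


# ---------------------------------------------------------------------------
# whole-dataset generation

def _default_tree(species: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating tree over the species with modest depth."""
    nodes = [f"{s}:{rng.uniform(0.05, 0.15):.4f}" for s in species]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        bl = rng.uniform(0.05, 0.15)
        nodes.append(f"({a},{b}):{bl:.4f}")
    merged = nodes[0]
    return f"{merged[:merged.rfind(':')]};"


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(AMINO_ACIDS[i]
                   for i in rng.integers(len(AMINO_ACIDS), size=length - 1))
    return "M" + body


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate assemblies, a reference panel, and the truth table.

    Each species receives ``loci_per_species`` planted loci on its first
    contig(s); remaining contigs are virus-free. The first
    ``n_paralog_pairs`` species carry one byte-identical duplicate pair
    (same paralog group). NS1 proteins diverge along the species tree;
    within a species, non-paralogous loci receive a few extra private
    substitutions so their proteins are distinct. With
    ``n_recombinants > 0``, extra loci whose ORFs are two-parent mosaics
    (single central breakpoint) are planted in the last species.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_aa = cfg.orf_len // 3 - 1

    species = [f"species_{i + 1:02d}" for i in range(cfg.n_species)]
    tree = cfg.divergence_tree or _default_tree(species, rng)

    root = _random_protein(n_aa, rng)
    # reference panel: three exogenous-like relatives of the root
    panel = {}
    for i in range(3):
        panel[f"ref_NS1_{i + 1}"] = mutate_protein(
            root, cfg.panel_rate * n_aa * (0.4 + 0.3 * i), rng)

    sp_protein = evolve_protein(root, tree, cfg.subs_rate, rng)

    contigs: dict[str, str] = {}
    species_of: dict[str, str] = {}
    truth: list[TruthRecord] = []
    flank = FlankSpec(cfg.left_flank_gc, cfg.right_flank_gc, cfg.flank_len)
    group_counter = 0
    seen_proteins: set[str] = set()

    def fresh_protein(base: str) -> str:
        # keep the start Met: the back-translated ORF must begin ATG
        p = "M" + mutate_protein(base, 3.0, rng)[1:]
        while p in seen_proteins:
            p = "M" + mutate_protein(base, 3.0, rng)[1:]
        return p

    for si, sp in enumerate(species):
        cids = [f"S{si + 1:02d}C{c + 1}" for c in range(cfg.contigs_per_species)]
        seqs = {cid: make_scaffold(cfg.contig_length, cfg.background_gc, rng)
                for cid in cids}
        # locus plan: all loci on contig 1; later contigs stay virus-free
        n_loci = cfg.loci_per_species
        paralog_pair = si < cfg.n_paralog_pairs
        base = sp_protein[sp]
        if base[0] != "M":
            base = "M" + base[1:]
        proteins: list[tuple[str, int]] = []      # (protein, group)
        if paralog_pair and n_loci >= 2:
            p = fresh_protein(base)
            seen_proteins.add(p)
            g = group_counter; group_counter += 1
            proteins += [(p, g), (p, g)]
            n_rest = n_loci - 2
        else:
            n_rest = n_loci
        for _ in range(n_rest):
            p = fresh_protein(base)
            seen_proteins.add(p)
            proteins.append((p, group_counter))
            group_counter += 1

        span = cfg.orf_len + 2 * cfg.flank_len
        slot = cfg.contig_length // max(n_loci, 1)
        if span + 200 > slot:
            raise ValueError("contig too short for requested locus count")
        contig = seqs[cids[0]]
        orf_by_group: dict[int, str] = {}
        for li, (prot, grp) in enumerate(proteins):
            if grp not in orf_by_group:
                orf_by_group[grp] = protein_to_nt(prot, rng,
                                                  gc_target=cfg.ns1_gc)
            orf = orf_by_group[grp]
            pos = li * slot + cfg.flank_len + 100
            strand = "+" if (si + li) % 2 == 0 else "-"
            contig, rec = plant_eve(contig, orf, pos, flank, rng,
                                    species=sp, contig_id=cids[0],
                                    strand=strand, paralog_group=grp)
            truth.append(rec)
        seqs[cids[0]] = contig
        for cid in cids:
            contigs[cid] = seqs[cid]
            species_of[cid] = sp

    if cfg.n_recombinants:
        truth += _plant_recombinants(cfg, rng, contigs, species_of,
                                     truth, flank)
    return SyntheticDataset(cfg, contigs, species_of, truth, panel, tree)


def _plant_recombinants(cfg, rng, contigs, species_of, truth, flank):
    """Mosaic loci combining the first two species' first ORFs."""
    out = []
    pa = truth[0].protein
    pb = next(t.protein for t in truth
              if t.species != truth[0].species)
    nta = protein_to_nt(pa, rng, gc_target=cfg.ns1_gc)
    ntb = protein_to_nt(pb, rng, gc_target=cfg.ns1_gc)
    grp_base = max(t.paralog_group for t in truth) + 1
    for r in range(cfg.n_recombinants):
        bp = (len(nta) // 2) // 3 * 3
        mosaic = make_mosaic(nta, ntb, [bp])
        # mosaic keeps ATG start and TAA stop; internal stops impossible
        cid = f"R{r + 1:02d}C1"
        sp = f"recomb_{r + 1:02d}"
        scaffold = make_scaffold(max(cfg.contig_length // 4,
                                     len(mosaic) + 2 * cfg.flank_len + 400),
                                 cfg.background_gc, rng)
        contig, rec = plant_eve(scaffold, mosaic, cfg.flank_len + 150, flank,
                                rng, species=sp, contig_id=cid,
                                strand="+", paralog_group=grp_base + r)
        contigs[cid] = contig
        species_of[cid] = sp
        out.append(rec)
    return out
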