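"""End-to-end orchestration of the mining and codivergence workflow.

Stages run in dependency order: simulate (optional) → search → mine →
catalogue → identity matrix / demarcation → flanks → dating →
recombination. Each stage writes its own outputs under the run
directory; a summary JSON collects the headline counts, and the
configuration is echoed alongside so every run is reproducible from its
own artefacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from eve_codiv import catalogue as cat
from eve_codiv import dating as dat
from eve_codiv import distances as dis
from eve_codiv import flanks as fla
from eve_codiv import recombination as rec
from eve_codiv.orfs import mine_assembly
from eve_codiv.search import search, write_outfmt6
from eve_codiv.synthetic import SimulationConfig, simulate_dataset

log = logging.getLogger("eve_codiv")

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    """Thresholds and stage toggles for one pipeline run.

    Defaults are the screening parameters the pipeline is built around:
    e-value ceiling 1e-5, minimum ORF 702 nt (~700 nt floor rounded to a
    codon multiple, stop included), 400 aa protein filter, 300 bp
    flanks, ICTV species demarcation at >85% identity / >80% coverage
    with a 35% genus floor, and the ≥3-method recombination consensus.
    """
    genomes_dir: str | None = None
    panel_fasta: str | None = None
    simulate: SimulationConfig | None = None
    evalue_max: float = 1e-5
    code: int = 9
    min_orf: int = 702
    min_protein: int = 400
    flank_len: int = 300
    species_id: float = 85.0
    species_cov: float = 80.0
    genus_floor: float = 35.0
    clade_cutoff: float = 55.0
    alpha: float = 0.05
    consensus_min: int = 3
    n_permutations: int = 1000
    calibrations: list = field(default_factory=list)
    outgroup: list = field(default_factory=list)
    tree_newick: str | None = None
    stages: dict = field(default_factory=dict)   # stage -> bool toggle
    seed: int = 0

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def _load_genomes(genomes_dir: str) -> tuple[dict, dict]:
    contigs, species_of = {}, {}
    for fa in sorted(Path(genomes_dir).glob("*.fasta")):
        for header, seq in _read_fasta(fa).items():
            if "|" in header:
                sp, cid = header.split("|", 1)
            else:
                sp, cid = fa.stem, header
            contigs[cid] = seq
            species_of[cid] = sp
    return contigs, species_of


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    summary: dict = {"seed": config.seed}

    # --- inputs -----------------------------------------------------------
    dataset = None
    if config.simulate is not None and config.enabled("simulate"):
        dataset = simulate_dataset(config.simulate)
        dataset.write(outdir / "synthetic")
        contigs, species_of = dataset.contigs, dataset.species_of
        panel = dataset.panel
        summary["n_planted"] = len(dataset.truth)
        log.info("simulate: %d contigs, %d planted loci",
                 len(contigs), len(dataset.truth))
    elif config.genomes_dir and config.panel_fasta:
        contigs, species_of = _load_genomes(config.genomes_dir)
        panel = _read_fasta(Path(config.panel_fasta))
    else:
        raise ValueError("either a simulate config or genomes+panel paths "
                         "are required")

    # --- search + mine ----------------------------------------------------
    if not config.enabled("search"):
        raise ValueError("downstream stages need the search stage enabled")
    hits = search(contigs, panel, evalue_max=config.evalue_max)
    write_outfmt6(hits, outdir / "hits.outfmt6.tsv")
    summary["n_hits"] = len(hits)
    log.info("search: %d hits", len(hits))

    loci = mine_assembly(contigs, panel, hits=hits, species_of=species_of,
                         code=config.code, min_len=config.min_orf)
    summary["n_loci"] = len(loci)
    log.info("mine: %d NS1 loci", len(loci))

    # --- catalogue --------------------------------------------------------
    report, unique = cat.dedup_identical(loci)
    summary["n_unique"] = report.n_unique
    summary["n_duplicate_groups"] = report.n_duplicate_groups
    with open(outdir / "dedup.json", "w") as fh:
        json.dump({"groups": report.groups, "n_input": report.n_input,
                   "n_unique": report.n_unique}, fh, indent=1)

    # --- identity matrix / demarcation ------------------------------------
    matrix = None
    proteins = {l.locus_id: l.orf.protein for l in unique}
    long_enough = {k: v for k, v in proteins.items()
                   if len(v) >= config.min_protein}
    if config.enabled("matrix") and len(long_enough) >= 2:
        matrix = dis.build_matrix(proteins, min_len=config.min_protein)
        matrix.to_tsv(outdir / "identity_matrix.tsv")
        clades = cat.assign_clades(matrix, cutoff=config.clade_cutoff)
        for l in unique:
            l.clade = clades.get(l.locus_id, "unassigned")
        rep_clade = {rep: clades.get(rep, "unassigned")
                     for rep, _ in report.groups}
        by_id = {l.locus_id: l for l in loci}
        for rep, members in report.groups:      # duplicates inherit clade
            for m in members:
                by_id[m].clade = rep_clade[rep]
        calls = []
        for i, a in enumerate(matrix.labels):
            for b in matrix.labels[i + 1:]:
                ident = matrix.identity(a, b)
                call = dis.classify_pair(
                    ident, 100.0, species_id=config.species_id,
                    species_cov=config.species_cov,
                    genus_floor=config.genus_floor)
                calls.append((a, b, ident, call.level))
        with open(outdir / "demarcation.tsv", "w") as fh:
            fh.write("a\tb\tidentity\tlevel\n")
            for a, b, ident, level in calls:
                fh.write(f"{a}\t{b}\t{ident:.2f}\t{level}\n")
        summary["n_clades"] = len(set(clades.values()))
        try:
            cs = cat.clade_stats(unique)
            summary["anova_identity_p"] = cs.anova_p["identity"]
        except ValueError:          # fewer than two clades of n >= 2
            pass

    _write_loci(loci, outdir)

    # --- flanks -----------------------------------------------------------
    if config.enabled("flanks"):
        recs = [fla.extract_flanks(l, contigs[l.orf.contig_id],
                                   flank_len=config.flank_len)
                for l in loci]
        try:
            fs = fla.flank_stats(recs)
            fs.site_map.to_csv(outdir / "flanks.tsv", sep="\t", index=False)
            fs.per_species.to_csv(outdir / "flank_gc_by_species.tsv",
                                  sep="\t")
            summary["gc_ns1_mean"] = fs.region_means["ns1"]
            summary["gc_left_mean"] = fs.region_means["left_flank"]
            summary["flank_t_p"] = fs.p_value
        except ValueError as exc:
            log.warning("flanks: %s", exc)

    # --- dating -----------------------------------------------------------
    if config.enabled("dating") and config.calibrations:
        newick = config.tree_newick
        if newick is None and matrix is not None and len(matrix.labels) >= 3:
            newick = _nj_newick(matrix)     # stand-in NJ tree, labelled so
        if newick:
            timed = dat.reltime(newick, outgroup=set(config.outgroup))
            cals = [dat.CalibrationPoint(tuple(c["mrca"]),
                                         float(c["age_mya"]),
                                         c.get("kind", "point"))
                    for c in config.calibrations]
            timed = dat.calibrate(timed, cals)
            with open(outdir / "node_ages.tsv", "w") as fh:
                fh.write("node\trelative_height\tage_mya\n")
                for row in timed.age_table():
                    fh.write(f"{row['node']}\t{row['relative_height']:.4f}"
                             f"\t{row['age_mya']:.2f}\n")
            summary["root_age_mya"] = max(timed.absolute_ages.values())

    # --- recombination ----------------------------------------------------
    if config.enabled("recombination"):
        seqs = {}
        if dataset is not None:
            by_len: dict[int, dict[str, str]] = {}
            for t in dataset.truth:
                nt = _truth_orf_nt(t, dataset.contigs[t.contig_id])
                by_len.setdefault(len(nt), {})[
                    f"{t.contig_id}:{t.orf_start}"] = nt
            seqs = max(by_len.values(), key=len) if by_len else {}
        if len(set(seqs.values())) >= 3:
            events = rec.scan_triplets(
                seqs, alpha=config.alpha,
                consensus_min=config.consensus_min,
                n_permutations=config.n_permutations, seed=config.seed)
            accepted = [e for e in events if e.accepted]
            summary["n_recombination_events"] = len(accepted)
            with open(outdir / "recombination.tsv", "w") as fh:
                fh.write("recombinant\tparents\tbreakpoints\tn_supporting"
                         "\taccepted\n")
                for e in events:
                    fh.write(f"{e.recombinant_id}\t{'+'.join(e.parent_ids)}"
                             f"\t{','.join(map(str, e.breakpoints))}"
                             f"\t{e.n_supporting}\t{e.accepted}\n")

    # --- truth comparison (synthetic runs) --------------------------------
    if dataset is not None:
        truth_keys = {(t.contig_id, t.orf_start, t.orf_end, t.strand,
                       t.protein) for t in dataset.truth}
        mined_keys = {(l.orf.contig_id, l.orf.start, l.orf.end,
                       l.orf.strand, l.orf.protein) for l in loci}
        summary["n_recovered_exact"] = len(truth_keys & mined_keys)
        planted_contigs = {t.contig_id for t in dataset.truth}
        summary["n_false_loci"] = sum(
            1 for l in loci if l.orf.contig_id not in planted_contigs
            or (l.orf.contig_id, l.orf.start, l.orf.end, l.orf.strand,
                l.orf.protein) not in truth_keys)

    _echo_config(config, outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def _truth_orf_nt(t, contig: str) -> str:
    from eve_codiv.synthetic import reverse_complement
    nt = contig[t.orf_start:t.orf_end]
    return reverse_complement(nt) if t.strand == "-" else nt


def _nj_newick(matrix) -> str:
    from skbio import DistanceMatrix
    from skbio.tree import nj
    d = 100.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    tree = nj(DistanceMatrix((d + d.T) / 2.0, matrix.labels))
    tree = tree.root_at_midpoint()
    for node in tree.traverse():        # NJ can emit small negative lengths
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree)


def _write_loci(loci, outdir: Path) -> None:
    with open(outdir / "loci.faa", "w") as fh:
        for l in loci:
            fh.write(f">{l.locus_id}\n{l.orf.protein}\n")
    with open(outdir / "loci.bed", "w") as fh:
        for l in loci:
            fh.write(f"{l.orf.contig_id}\t{l.orf.start}\t{l.orf.end}"
                     f"\t{l.locus_id}\t0\t{l.orf.strand}\n")
    with open(outdir / "loci.tsv", "w") as fh:
        fh.write("locus_id\tcontig\tstart\tend\tstrand\tspecies"
                 "\tbest_subject\tidentity\tcoverage\tclade\n")
        for l in loci:
            fh.write(f"{l.locus_id}\t{l.orf.contig_id}\t{l.orf.start}"
                     f"\t{l.orf.end}\t{l.orf.strand}\t{l.species}"
                     f"\t{l.best_subject}\t{l.confirm_identity:.2f}"
                     f"\t{l.confirm_coverage:.2f}\t{l.clade}\n")


def _echo_config(config: PipelineConfig, outdir: Path) -> None:
    d = dataclasses.asdict(config)
    if config.simulate is not None:
        d["simulate"] = dataclasses.asdict(config.simulate)
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
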