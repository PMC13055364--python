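# Methods

This note documents the models and procedures implemented in
`eve_codiv`, the defaults that matter, the design choices that were
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Homology search

Contigs are translated in all six frames (standard code — the reference
panel consists of standard-code viral proteins; the alternative genetic
code matters only at ORF re-translation) and aligned locally against
each panel protein under BLOSUM62 with affine gaps (open −11, extend −1;
a gap of length k costs open + (k−1)·extend). Significance follows the
Karlin–Altschul expectation E = K·m·n·exp(−λS) with the published gapped
BLOSUM62 parameters λ = 0.267, K = 0.041 (configurable); m is the frame
translation length and n the summed panel length. Hits with E above the
ceiling (default 1e−5) are dropped.

Two execution modes share this contract. The exact mode runs a full
Smith–Waterman per frame × subject. The default mode first collects
exact k-mer seeds (k = 6, ≥ 2 seeds) shared with the subject, pools
nearby seeds, and extends only around seeded windows — this is what
makes multi-100-kb assemblies a minutes-scale problem, finds each
seeded locus independently (several loci of one frame all surface),
and agrees with the exact mode on every planted locus in the test
suite. The exact mode reports only the single best alignment per
frame × subject; use the seeded mode when one frame may contain
several loci.

Overlapping hits (> 50% of the shorter interval, same contig) are pooled
into loci and only the best-scoring subject per locus is kept
(score, then lexicographic subject id, then coordinate — deterministic
under input reordering).

## ORF mining under the flatworm mitochondrial code

"Flatworm mitochondrial" is mapped to NCBI translation table 9
(AAA→Asn, AGA/AGG→Ser, TGA→Trp relative to the standard code; stops TAA
and TAG); table 14 is selectable. Within each frame, segments are
bounded by stop codons and the 5′-most ATG of a segment opens the
reported ORF. The minimum ORF length is 702 nt including the stop codon
— a ~700 nt floor rounded up to a codon multiple. ORFs running off the
contig edge (no stop) are not reported, and a hit whose contig carries
no qualifying ORF around it is dropped. The mined protein excludes the
stop; a hit is assigned to the ORF covering ≥ 80% of its interval on
the same strand (ties: longer ORF, then smaller start). Confirmation
aligns the mined protein back to the panel and records percent identity
over alignment columns and percent of the subject covered.

## Catalogue statistics

Loci with byte-identical proteins are paralogous copies of one
integration lineage; they are collapsed to the lexicographically
smallest locus id before comparative analyses. Clade labels are either
supplied or derived by single-linkage clustering of the identity matrix
at a 55% cutoff. Identity/coverage contrasts between clades use
classical one-way ANOVA (no Welch correction; a flag enables it) and
Tukey HSD adjusted p-values, both delegated to scipy.

## Identity matrix and taxonomy demarcation

Pairwise identity is computed SDT-style: global Needleman–Wunsch
(BLOSUM62, gap open 10 / extend 0.2, same gap-length convention as
above) and identity = matches / columns-with-at-least-one-residue, so a
gap opposite a residue counts as a difference and dual-gap columns are
skipped; `--ignore-gaps` gives the residue-columns-only alternative.
Sequences shorter than 400 residues are excluded before matrix
construction to avoid alignment artefacts on fragments. Display order
comes from midpoint-rooted neighbour joining on (100 − identity) — a
layout device, not a phylogenetic claim.

Demarcation applies the ICTV Parvoviridae rules: same species iff
identity > 85% and coverage > 80% (both strict); genus membership at
identity ≥ 35% — the published band is 35–40%, and the floor is a
configuration value precisely because the band is ambiguous; below the
floor the pair is distinct. A focal sequence under 75% identity to all
other members is flagged as a candidate new species. Alignment-column
trimming for downstream users drops columns whose modal non-gap residue
is carried by < 50% of non-gap rows.

## Flanking-sequence integration evidence

For each locus the 300 bp up- and downstream of the ORF are extracted
following the ORF's own orientation (minus-strand loci take the genomic
right interval, reverse-complemented, as their upstream flank), and
truncated at contig edges. GC is 100·(G+C)/(A+C+G+T), ambiguity codes
excluded from both numerator and denominator, undefined when no
unambiguous base remains; it is strand-invariant. Flanks shorter than
50 nt are reported but excluded from inference — their GC is too
variable to be meaningful. Integration evidence is a paired t-test of
each locus's coding-region GC against its own upstream-flank GC: an
integrated element keeps its viral composition inside host sequence of
a different regime, so the mean paired difference is the effect of
interest.

## Relative-rate dating

A rooted tree with substitutions/site branch lengths is converted to
relative node times without a global clock. Bottom-up, at every node
the two descendant lineage lengths L_i (stem branch plus the child's
already-corrected mean tip path) are equalised by relative rates
r_i = 2L_i/(L_1+L_2), making the node's local height (L_1+L_2)/2;
corrections propagate multiplicatively toward the tips, so a node's
height is its local height divided by the product of rates along its
root path, and each branch's lineage rate is that cumulative product.
Heights are normalised to the root (= 1). Ultrametric input yields all
rates 1 and heights equal to node depths; scaling all branch lengths by
a constant leaves heights unchanged; heights strictly decrease along
every root-to-tip path. Polytomies are resolved arbitrarily with
zero-length branches; zero-length lineages take rate 1 (their subtrees
have zero depth regardless).

Calibrations are node ages in MYA (here: host divergence times) given
as tip pairs. Point calibrations fit the single scale from relative
height to age by least squares through the origin,
s = Σ t_i·a_i / Σ t_i²; maximum-age calibrations are checked afterwards
and violations reported, not enforced. Outgroup tips (which must be
monophyletic at the root) are excluded from estimation entirely —
ingroup rates are not assumed to transfer — so outgroup-side nodes
carry no heights or ages, while the ingroup root is timed. Confidence
intervals are not computed. When no tree is supplied, the pipeline can
fall back to a midpoint-rooted NJ tree from the identity matrix; this
is labelled a stand-in and is not a substitute for a proper
phylogenetic estimate.

On simulation, 32-tip trees with per-branch lognormal rate multipliers
(log-SD 0.15) are dated with a median node-age relative error of ~3%
over 100 replicates; clock trees are recovered to arithmetic precision.

## Recombination scanning

Three detectors run per (recombinant, parent A, parent B) triplet on an
aligned set:

* **MaxChi** — on sites where the parents differ and the recombinant
  matches exactly one of them, the recombinant is coded A/B; every
  candidate breakpoint contrasts A-match counts in equal flanking
  windows (default 15 informative sites) with a 2×2 chi-square, and the
  maximum over breakpoints is the statistic.
* **Chimaera** — identical machinery on sites where the recombinant
  differs from exactly one parent.
* **BootScan-like** — sliding-window p-distances (default 200 nt window,
  50 nt step) from the recombinant to each candidate; switch points are
  nearest-parent changes persisting ≥ 2 windows. The test statistic is
  the largest window-wise advantage any rival takes over the globally
  nearest candidate: it is exactly zero (p = 1) when one parent leads in
  every window, and it grows directly with mosaic signal.

All three take permutation p-values by shuffling the exchangeable unit
under the no-recombination null — informative-site order for the
chi-square detectors, alignment columns for the window scan (windows
overlap, so the nearest-parent track itself is autocorrelated and may
not be permuted directly; shuffling columns and recomputing the windows
sidesteps that). p = (1 + #{perm ≥ obs}) / (1 + N), N = 1,000 by
default. Measured at N = 200 over 200 null replicates, per-detector
type-I error is 3.5–7% at nominal 5%.

`scan_triplets` collapses duplicate sequences, enumerates all triplets,
Bonferroni-corrects over triplets × methods, and accepts an event only
when at least `consensus_min` = 3 detectors — i.e. all three — fall
below α = 0.05 after correction. This is deliberately stricter than a
3-of-7 rule over seven detectors: with three methods, consensus means
unanimity. Planted single-breakpoint mosaics with ~30 informative sites
per side are accepted in ≥ 80% of replicates with the breakpoint
localised within one window.

## Structure comparison

Models are read from PDB/mmCIF (first protein chain; optional JSON
sidecar with pTM/ipTM). Quality control keeps models with pTM > 0.5 and
ipTM > 0.8, both strict; models without metadata pass with a warning.
Residue correspondence comes from a global sequence alignment of the
two models. Superposition is the Kabsch algorithm — closed-form
least-squares rotation via SVD with the determinant sign corrected so
reflections are never used. Two paired points are accepted (the minimum
with a well-defined optimum); rank-deficient configurations fall back
to a +1 sign. Global RMSD uses all corresponded Cα with no outlier
rejection by default (an align-style rejection cycle is available by
flag). Domains are delineated by a 5 Å spatial screen from seed
residues — by default Walker-A motif matches (G-x(4)-G-K-[TS]) anchor
the ATPase domain; any residue with an atom within the cutoff of a seed
atom joins, and contiguous runs shorter than 3 residues are pruned
unless they contain a seed (a lone seed is never discarded). Similarity
classes: RMSD ≤ 2.0 Å highly similar, ≤ 3.0 moderately similar, > 3.0
significantly divergent.

## Synthetic data: what it emulates, and what it does not

The generator produces multi-contig assemblies (i.i.d. background
composition), plants back-translated NS1 ORFs with the compositional
signature of real integrations — coding regions tuned to 41.84% GC by
synonymous-codon swapping, upstream flanks at 15.52% GC, downstream at
44% — evolves NS1 proteins along a known species tree by Poisson
substitution, duplicates loci into byte-identical paralog pairs, and can
plant two-parent mosaic ORFs for the recombination stage. Back-translation
uses only codons that read identically under the standard and flatworm
mitochondrial codes, so the planted protein is what both the search
(standard code) and the miner (table 9) see; a flag emits standard-code
ORFs with a TGA stop as a negative control for code handling.

Two pieces of ground-truth hygiene are deliberate: the upstream flank is
sanitised so that, reading in frame away from the start codon, no ATG
precedes the first stop — offending codons are resampled from the
flank's own composition (GC bias < 0.05 points), otherwise a random
upstream ATG would extend the true ORF in a sizeable fraction of AT-rich
flanks and locus recovery would measure flank luck, not the miner. And
per-locus private substitutions always preserve the start Met.

What passing the synthetic benchmark does **not** show: performance on
degraded or frameshifted EVEs (the miner requires an intact ATG→stop
frame), repeat- or transposon-rich integration contexts, codon-usage
realism, indel evolution (the protein evolver is substitution-only, so
planted families are natively aligned), or assembly artefacts such as
N-runs — real flanks with many Ns yield undefined GC and are excluded
from the paired test by the ambiguity rule.

## Numerical and procedural choices

* Alignment is delegated to a C implementation of Gotoh's algorithm;
  test oracles re-implement exhaustive DP independently and require
  exact score agreement on small inputs.
* All randomness flows through `numpy.random.default_rng` from a single
  integer seed; a fixed configuration reproduces byte-identical FASTA
  and TSV output.
* Tie-breaks are lexicographic throughout (subject ids, locus ids,
  representative choice), making results invariant to input order.
* The pipeline's stage outputs are plain text (FASTA, BED6, outfmt-6
  TSV, newick, YAML, JSON); each run echoes its full configuration.
* Study-scale defaults keep the whole synthetic benchmark and the
  reproduction script in the minutes range on a single CPU: 10 species ×
  2 × 100 kb, 30 loci; 100 dating replicates; 200 recombination null
  replicates at 200 permutations (1,000 remains the analysis default).

## Known limitations

* The seeded search can miss loci diverged far beyond the seed model
  (< ~50% identity gives few exact 6-mers); the exact mode has no such
  limit but reports one locus per frame × subject.
* The relative-rate recursion implements the core estimator only — no
  rate-merging heuristics and no confidence intervals.
* The recombination consensus requires unanimity of three detectors and
  is conservative by construction; single-method signals are reported
  but never accepted.
* Demarcation coverage is taken from panel confirmation, not from the
  pairwise matrix, when classifying mined loci.
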