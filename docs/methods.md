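# Methods

`mitochar` characterizes a vertebrate mitochondrial genome from its sequence
and gene table, and places it phylogenetically from per-gene alignments. This
note records the models, conventions and design decisions behind each stage,
and what the synthetic-data tests do and do not demonstrate.

## Coordinate model and feature accounting

Coordinates are 1-based and inclusive at both ends, the convention of
published mitogenome gene tables; the circular molecule is linearized at the
conventional origin (tRNA-Phe start). A feature may wrap across the origin
only when its `wraps` flag is set (`start > end`); none of the canonical
features wrap. Internally no 0-based half-open representation leaks into I/O.

Signed intergenic gaps are `start(downstream) − end(upstream) − 1` over
start-sorted adjacent features, with a closing record joining the last
feature back to the first; negative values are overlaps, common in
mitogenomes (ATP8/ATP6 overlap by 10 bp, ND4L/ND4 by 7 bp). The spacer
census sums strictly positive gaps, excluding by name the two locations the
published accounting leaves out: the replication-origin gap between tRNA-Asn
and tRNA-Cys and the control region itself.

The light-strand replication origin (O_L) is modeled as the gap between
tRNA-Asn and tRNA-Cys rather than as a feature row, so the shipped canonical
table reproduces the published +37 intergenic value and the spacer census can
exclude it by the flanking-pair name.

### The shipped canonical table

The packaged gene table (`data/bahaba_features.tsv`) is the published
38-row Chinese bahaba arrangement with three reconciliations where the
published table is internally inconsistent, each noted in the file header:

* **tRNA-Trp strand** — printed as L, but the genome is described as having
  8 L-strand tRNAs (14 H), which is also the canonical vertebrate
  arrangement; the table carries H.
* **ND6 coordinates** — the printed start (13794) would overlap ND5 by 4 bp,
  while the printed intergenic column and the published spacer census
  (36 bp over 11 locations, spacers 1–8 bp) require a +4 spacer after ND5;
  the table carries 13802–14323, preserving the printed 522 bp size.
* **ND2 / ND3 stop classes** — printed sizes (1046/349) contradict their own
  printed coordinates (4055–5099 → 1045; 9656–10005 → 350); the table
  carries the stop classes consistent with the coordinate lengths (T and
  TA). Coordinates always win over declared sizes; the validator reports
  such conflicts (e.g. the text-quoted 947/1684 bp rRNA sizes versus the
  coordinate-derived 949/1702 bp) as warnings, never errors.

The parser itself preserves whatever an input file declares; only the
shipped table is reconciled.

## Composition and strand skew

Base composition is counted exactly; `N` is tallied separately and excluded
from the denominator, any other character is an error naming its offset.
Strand asymmetry on the heavy strand is

    GC-skew = (G − C) / (G + C),    AT-skew = (A − T) / (A + T),

computed from raw counts (full precision) with an independent
percentage-based entry point for checking printed tables; both agree to
three decimals on any profile because the statistic is scale-free. A zero
denominator yields an explicit undefined value (`None`), never a silent 0.

Stop codons follow the vertebrate mitochondrial reading (NCBI translation
table 2, AGA/AGG as stop, carried as data so it can be overridden): a gene
whose length is ≡ 2 (mod 3) ends on an incomplete TA, ≡ 1 (mod 3) on a lone
T — both completed to TAA by post-transcriptional polyadenylation — and a
codon-complete gene ends on TAA/TAG/AGA read from the sequence when
available. Translated residues are `(length − stop_length) / 3`; this
reproduces the published residue counts for the eleven protein rows whose
printed length, stop and residue count are mutually consistent (ND2 and ND3
are printing errors: computation gives 348 and 116).

## Control-region annotation

The teleost control region is organized as ETAS domain → central conserved
domain (CSB-F, CSB-E, CSB-D) → conserved sequence block domain (CSB-1/2/3).
Blocks are located by a Hamming-distance consensus scan on the CR sense
strand only (all published blocks lie on that strand). Mismatch budgets are
configuration, not biological fact — the literature gives none: the default
is 0 for the short, low-complexity blocks (the 7-nt ETAS core and
palindrome, CSB-2, CSB-3) and 2 for the 17–22-nt blocks (CSB-F/E/D, CSB-1).
Ties break by fewest mismatches, then leftmost start, so output is
deterministic. The ETAS "palindrome" is a strict position-wise base
complement of the core (TACATAT / ATGTATA) — not a reverse complement — and
is checked in exactly that sense.

Domain intervals must tile the CR without gaps, so the boundaries are:
ETAS domain `[1, CSB-F start − 1]`, central conserved domain
`[CSB-F start, CSB-1 start − 1]`, CSB domain `[CSB-1 start, CR end]`.
(Anchoring the central domain's right edge at CSB-D's end instead would
leave an unassigned stretch before CSB-1; the tiling definition keeps every
CR position in exactly one domain while preserving the anchor order.)
A motif absent at its budget leaves the annotation marked partial; the
order flag requires all seven blocks present in strictly increasing
positions.

## O_L stem-loop detection

The hairpin search is purely combinatorial: among all structures with a
contiguous, fully paired stem (no bulges or internal loops, matching the
simple published structure) and a loop between `min_loop` (default 3 nt, the
steric minimum) and `max_loop` (default 30 nt), it returns the structure
maximizing stem pairs, ties broken by smaller loop and then smaller 5′ tail.
Pairing is Watson–Crick with an off-by-default G·T wobble flag (the
published structure needs none). No free-energy model is attempted.

The published description of the O_L — "20 bp in the stem and 13 bp in the
loop" for a 37-nt sequence — is arithmetically possible only if "20 bp"
means 20 stem *nucleotides*, i.e. 10 base pairs (10·2 + 13 + 4 = 37). The
detector, and an independent brute-force enumeration over every
(outer pair, stem length) decomposition, both return exactly that 10-pair,
13-nt-loop structure with a 4-nt 5′ tail on the printed sequence.

## Phylogenetics

Preparation follows standard mitogenome practice: ND6 is dropped (anomalous
base composition), terminal stop codons — complete or incomplete, classified
by alignment length mod 3 — are trimmed from protein alignments, and third
codon positions are excluded. The supermatrix concatenates the remaining
first/second codon-position columns and the rRNA genes into three labeled
partitions (`codon1`, `codon2`, `rRNA`); partition maps are written in
RAxML-style text. rRNA column filtering ("unambiguously aligned" sites) is
left to the user: no filtering criterion is inferred.

**Saturation.** For every taxon pair the proportions of transition (A↔G,
C↔T) and transversion differences per compared site are reported (pairwise
deletion of gaps/ambiguity). The plateau diagnostic regresses transition
proportion against the JC-corrected divergence over the pairs in the upper
half of the observed p range; the corrected distance is the right x-axis
because observed proportions are bounded while the corrected divergence
keeps growing, so the slope decays toward zero as substitutions accumulate.
(Against p itself the slope is uninformative: under Jukes–Cantor the
transition proportion is p/3 at every divergence.) A slope below the
threshold (default 0.2, configurable) flags saturation, as does any pair at
or beyond the p = 3/4 correction ceiling. This is a bespoke statistic, not
a reimplementation of DAMBE's index test.

**Distances and trees.** Pairwise distances use the standard closed forms
(p, JC69 `−¾ ln(1 − 4p/3)`, K80 from transition/transversion proportions),
with pairwise deletion and explicit flagging of pairs whose logarithms
overflow. Tree inference is neighbor joining (delegated to scikit-bio),
with negative branch lengths clamped to zero under a warning. The published
study's Bayesian (MrBayes) and maximum-likelihood (PAUP, GTR+I+G) analyses
are deliberately not re-implemented; NJ plus bootstrap is this package's
inference engine, and topology-level claims are validated by
simulation-recovery tests rather than by reproducing published support
values (which would require the real GenBank accessions). The bootstrap
resamples columns with replacement *within* each partition, preserving
partition sizes; each replicate runs the same distance + NJ route, and the
50% majority-rule consensus (dendropy) carries support as the percentage of
replicates containing each split. The seed is mandatory whenever
bootstrapping, and identical seeds give byte-identical Newick output.

## Synthetic data

`generate_mitogenome` emulates the published genome's structure with known
truth: the canonical 37-gene layout at 16,500 bp, i.i.d. background bases at
the published overall composition (T 25.1 / C 31.4 / A 27.6 / G 15.9 %),
ATG starts and declared stops written into protein genes strand-aware (the
real ND5/ND6-style stop overlaps are representable because complementary
reading frames share bases), the seven CR blocks planted at recorded
offsets in a background rejection-sampled to be motif-free (so planted
positions are provably the unique best hits), and a stem-loop of exact
geometry in the O_L gap. The hairpin sequence uses disjoint base alphabets
for tails/arms/loop (A^f C^s T^l G^s A^r) so the planted geometry is the
unique maximum; it is a structural cartoon, not a realistic O_L sequence.
Codon/motif/hairpin overrides touch ~1.6% of the genome, so realized
composition stays within one percentage point of target (binomial sampling
alone contributes ~0.3 points at this length).

`simulate_alignment` evolves sites independently along a user tree under
JC69/K80/HKY (transition matrices by `expm` of the normalized generator,
root drawn from the stationary frequencies), with per-partition rate
multipliers applied as branch-length scalars per site class (codon position
or rRNA).

What passing tests on these data do **not** show about real data: there are
no indels or alignment error (rows are generated aligned), no rate
heterogeneity beyond the partition multipliers (no +I+G), no tandem repeats
or heteroplasmy in the CR, tRNAs are compositionally unstructured, and the
planted motifs are exact consensus copies — real blocks diverge from
consensus, which is why the mismatch budgets exist and are configurable.

## Numerical choices and degenerate inputs

* Percentages render with one decimal (matching published tables); JSON
  reports keep full precision; skews render with three decimals.
* Empty feature tables, tables without tRNAs, all-gap pairs, zero-length
  branches, and consensus-longer-than-sequence scans all have defined
  behavior (error, skip-and-report, identity, or empty result — never a
  silent wrong number).
* All generators and the bootstrap are pure functions of their integer seed
  (NumPy `default_rng`).

## Problem sizes

Test and acceptance runs are sized for deterministic, fast verification:
motif-scanner and hairpin oracles run on 1,000 and 600 random instances;
NJ recovery uses 20 seeds at 2,500 sites on a 6-taxon tree with 0.03
substitutions/site internal edges; the bootstrap demonstration uses an
11-taxon tree, 5,000 pre-strip columns and 100 replicates; divergence
calibration uses 100,000 sites. The full suite runs in a few seconds.

## Known limitations

* NJ is statistically consistent but not the published inference method;
  support values are bootstrap proportions under a distance model, not
  posterior probabilities.
* The saturation diagnostic assumes the JC correction for its x-axis; under
  extreme base-composition bias the corrected axis compresses.
* GenBank input is read-only and limited to CDS/tRNA/rRNA/D-loop features.
* De novo gene annotation and tRNA cloverleaf folding are out of scope:
  gene boundaries come from the table, as in the source study.
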