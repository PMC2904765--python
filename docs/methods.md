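# Methods

This note documents the models, conventions and design choices behind
`dazfam`, in the order the pipeline runs them, together with what the
synthetic benchmark does and does not establish about real data.

## Sequence conventions

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted at the parsing boundary only, and minus-strand exon
lists are re-ordered to transcript orientation on read.  Translation uses
the standard nuclear genetic code (table 1) throughout — none of the taxa
this pipeline is aimed at requires an alternative nuclear code for these
loci.  Codons containing `N` translate to `X`; stops are `*` and are
permitted only as a trailing marker in protein containers (the six-frame
translator uses a relaxed container, since genomic frames are full of
internal stops).  Molecular weights use average (not monoisotopic) residue
masses plus one water; the classifier's size criteria operate at "around
30 kDa" granularity, where the distinction is irrelevant.

## Pairwise and multiple alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment share one
affine-gap Gotoh engine operating on an arbitrary score matrix.  Fixed
conventions, chosen for determinism and declared rather than inherited from
any particular tool:

* substitution matrix BLOSUM62; gap open 10, gap extend 0.2 (the ClustalW
  protein defaults); a gap of length L costs `open + extend × L`, i.e. the
  GOP is charged once at opening and the GEP per gapped position;
* traceback tie-break: diagonal, then up (gap in the second sequence), then
  left; float comparisons use an epsilon of 1e-9;
* the local-alignment start cell is the maximum-score cell first in
  row-major order; score 0 is a valid "no hit".

The engine is validated two independent ways in the test suite: exhaustive
enumeration of all alignments for short sequences, and Biopython's
`PairwiseAligner` configured to the same gap convention.

Progressive multiple alignment follows the ClustalW recipe at small-n
scale: a guide order from neighbor joining on p-distances of all pairwise
global alignments, then profile–profile merges in that order
("once a gap, always a gap").  Profile columns score as expected
substitution scores (frequency-weighted BLOSUM62; gaps contribute zero).
No iterative refinement is attempted — inputs here are a dozen homologous
RRMs, not thousands of divergent sequences.

## Consensus profiles and family signatures

A consensus profile records per-column residue frequencies over non-gap
residues.  Columns with more than 50% gaps are dropped and recorded.  The
majority call breaks frequency ties alphabetically; an alternate residue is
emitted when its frequency is ≥ 0.25 and the majority is below 0.9,
rendered in parenthesised notation (`PNRI(V)FVGG`).  The two thresholds are
package defaults: the notation convention they encode (a second residue
shown only when it is common and the column is genuinely polymorphic) is
standard, the precise cutoffs are not fixed by any source.

A family signature carries the RNP2/RNP1 patterns (with per-position
alternate sets), the deletion flag (true only for DAZL, whose RRM is two
residues shorter), a size window, and the junction template — internal
exon–intron junctions as codon offsets from the RRM start, canonically
three for BOULE.

## Translated search

The discovery stage re-implements the Tblastn idea exactly rather than
heuristically: all six frames of each target are translated with coordinate
maps back to forward-strand codon spans, and the consensus query is aligned
to each frame by full Smith–Waterman.  Ranking is by raw score; no
Karlin–Altschul statistics (target sets here are single genomes or small
benchmark sets, where an exact scan is affordable and removes
BLAST-version dependence).

The default score threshold is 20% of the query self-score.  Calibration
rationale: in an exonized gene the ~92-aa RRM is split into ~20–25-aa
exon fragments, so the best single-frame hit on a real gene ranges from a
single exon fragment (~17% of self-score) to an intron-bridged chain of
exons (up to ~70%); the maximum local score of the same query against
random background sequence of benchmark size (8 kb) is ~10% of self-score.
20% separates the two regimes with margin on both sides.  Hits on the same
target and strand overlapping by more than half the shorter span are
merged, keeping the higher score.

Reciprocal-best-hit validation aligns a candidate against a labeled
reference proteome; the call is confirming only when the unique top-scoring
reference belongs to the claimed family.

## Classification ladder

For each candidate, in order:

1. **Locate the RRM** by local alignment of each family consensus; both
   below 50% of the consensus self-score → `NOT_HOMOLOG`.  The RRM start is
   extrapolated back to consensus column 0 from the first aligned column,
   so edge clipping at high divergence does not shift downstream
   coordinates.
2. **RNP signatures**: mismatches against RNP2+RNP1 patterns (majority or
   alternate matches; gaps never match).  A family passes at ≤ 2 combined
   mismatches; a DAZL pass additionally requires the 2-column deletion
   (detected by global alignment against the BOULE consensus, a gap of
   exactly 2 columns within ±2 columns of the template site).  Exactly one
   passing family → tentative call.
3. **Corroboration**: size inside the family window (15–45 kDa, applied
   only to complete sequences — wide enough that a genuine ~22 kDa homolog
   passes), exactly one RRM located in the N-terminal half (iterative
   masked re-search), ≥ 2 template junctions shared when a gene model is
   available (each junction's RRM-relative codon offset within ±1 codon of
   an unclaimed template offset; the 2-of-3 floor accommodates a known
   exon fusion), and a confirming reciprocal best hit when a reference
   proteome is supplied.  Any failure downgrades to `DIVERGENT_PARALOG` —
   the treatment a lineage-specific divergent duplicate receives — rather
   than `NOT_HOMOLOG`.
4. Candidates whose RRM aligns but whose best family accumulates 3–6 motif
   mismatches are likewise `DIVERGENT_PARALOG`; beyond 6, `NOT_HOMOLOG`.
   Absent inputs (no gene model, no proteome) skip their criterion instead
   of failing it.

The 2-mismatch budget quantifies a qualitative distinction
("identical motifs" versus "multiple differences in critical positions");
it is a declared default, monotone in the sense that widening it never
turns a family call into `NOT_HOMOLOG`.

## Phylogenetics

Protein distances use pairwise deletion of gap columns; the default model
is the Poisson correction `d = −ln(1 − p)` (matching the
substitutions-per-site scale of distance trees in this literature), with
plain p-distance available.  A pair with p ≥ 1 is saturated and is an
error; bootstrap replicates containing one are dropped and counted.

Neighbor joining is the Saitou–Nei Q-criterion algorithm; ties join the
lowest-index pair; negative branch-length estimates are clamped to zero and
counted on the tree.  On additive matrices it recovers topology and branch
lengths exactly (tested against brute-force minimum evolution over all 15
five-taxon topologies).  Bootstrap supports resample columns with
replacement; each replicate's RNG derives from (master seed, replicate
index), so supports are independent of evaluation order.  Support values
attach to internal nodes as percentages; bipartition comparison is
topology-only.  Outgroup rooting inserts the root at the midpoint of the
outgroup's pendant edge.

## Ka/Ks (NG86 + Jukes–Cantor)

The estimator is Nei–Gojobori (1986) with equal-path weighting: fractional
synonymous sites per codon from the nine single-nucleotide neighbors
(mutations to stop codons count as nonsynonymous sites, so S + N = 3 per
codon); difference counts averaged over all minimal mutational pathways,
excluding pathways through stops whenever a stop-free alternative exists
(if none exists, stop-touching steps count as nonsynonymous).  Proportions
are corrected with Jukes–Cantor, `d = −(3/4) ln(1 − 4p/3)`; p ≥ 3/4 is
reported as saturation.  Codon columns with a gap in either row are
pairwise-deleted.  Sentinels: Ka = Ks = 0 reports a `0/0` ratio (treated
as 0 with a flag); Ks = 0 with Ka > 0 reports infinity.  Selection calls
follow the conventional thresholds: ratio > 1 positive, < 0.1 purifying,
otherwise unresolved.

NG86 with equal pathway weighting is the simplest estimator consistent with
reporting one Ka/Ks per sequence pair; modified-NG (transition/transversion
weighted) or ML codon models would give different per-pair values.  The
test suite pins the counting core to an independent enumeration oracle over
all 61×61 sense-codon pairs and cross-checks whole-pair estimates against
Biopython's NG86.

## The synthetic-data generator

The generator is the benchmark's source of truth.  A root CDS of 250
codons (default) carries a 92-codon RRM at codon 60 with RNP2 at RRM
offset 12 and RNP1 at offset 60; it evolves along a user-supplied tree by
acceptance–rejection: point mutations are proposed uniformly
(codon × position × alternative nucleotide) at `branch length ×
n_codons` expected proposals — branch lengths are therefore expected
*proposed* mutations per codon — and accepted with probability 1 if
synonymous, ω if nonsynonymous, 0 if creating a stop.  Three nested
constraint levels: ω for flanks, ω_core = 0.01 for the RRM, ω_motif = 0.01
for the RNP positions themselves (the most conserved residues of a real
RRM, which is precisely why they work as signatures; the hard preset
relaxes the core to 0.25 while keeping motifs at 0.05).

One correction makes the generator honor its contract exactly: plain stop
rejection would depress the realized dN/dS to ω·(9−s−t)/(9−s) per codon
(s, t = synonymous and stop neighbors), because the standard site
convention books stop-bound opportunities as nonsynonymous sites that the
process never realizes.  Synonymous acceptances are therefore thinned by
the same per-codon factor, making realized dN/dS per site equal ω codon by
codon.  The scheme remains deliberately simple — uniform proposals, no
61×61 rate matrix, not time-reversible — and is exactly the process NG86
models, which is what makes parameter-recovery tests sharp.

A labeled branch founds the DAZL family: its RNP codons are rewritten to
the DAZL motifs and two codons are deleted at a fixed RRM position, so
deletion-bearing leaves and only those are DAZL in truth.  Leaf CDSs are
exonized at fixed junction offsets (default junctions at codons 20, 80,
105, 130 → five exons, three junctions internal to the RRM), introns are
random-length (60–200 nt) with GT..AG ends, and each gene is embedded at a
random position — strands alternating across leaves so both are always
exercised — in random background sequence (8 kb, GC 0.42).  Splicing each
written gene model back out of its genome must reproduce the CDS exactly;
this is asserted at generation time.

RNG policy: one master seed; per-branch and per-leaf streams derive by
stable hashing of node labels, so adding taxa does not perturb existing
lineages (tested).

**What the benchmark does not emulate**: insertion/deletion variation
outside the single diagnostic deletion (indel rate defaults to 0; the
aligners are tested on gapped inputs separately), realistic splice-site or
intron-length models, repeat content and compositional heterogeneity of
real genomes, transition/transversion bias, and among-site rate variation
beyond the three-level ω mask.  Passing benchmarks therefore shows the
pipeline's logic and estimators are correct under their own model
assumptions at realistic sizes — not that the thresholds are optimal for
any particular real genome.

## Benchmark presets and observed performance

`default`: 12 leaves (7 BOULE, 5 DAZL) at mild divergence (branch lengths
0.04–0.12, flank ω 0.1); training members feed signature derivation,
held-out members plus signature-scrambled and random negatives form the
classification set.  `hard`: 8 leaves on long branches with the RRM core
relaxed to ~20% within-RRM divergence; the documented floor on this preset
is ≥ 50% correct family calls and ≥ 75% search recall with still zero
false BOULE calls (observed: 75–100% correct calls across seeds —
divergent members downgrade to `DIVERGENT_PARALOG`, they do not flip
family).  `null`: background genomes only; the search stage must return
nothing.

## Problem sizes

Suite-wide sizes are chosen so the full test run finishes in about a
minute and the acceptance script in under a minute on one CPU: benchmark
genomes 8 kb, proteins 250 aa, 20 replicates per ω for estimator recovery
at 1000 codons, 50 random additive matrices for NJ recovery, and
200–500 bootstrap replicates in the analysis drivers.

## Known limitations

Ranking without E-values means score thresholds must be recalibrated for
target sizes far beyond the benchmark scale (tens of Mb).  NG86 is a
counting estimator: it saturates near p = 3/4 and its equal-path weighting
is slightly conservative at high divergence.  The progressive aligner has
no refinement pass and will propagate early errors on sets far more
divergent than these families.  The classifier's junction criterion
assumes gene models whose junction phases are trustworthy; on real
annotations, junction offsets inherit annotation error.  The accession
workflow (fetching GenBank records for the real homolog set) is not part
of the offline pipeline; the modules accept any FASTA/GFF3 inputs with the
documented conventions.
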