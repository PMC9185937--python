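# Methods

## The model

A plant mitochondrial genome is represented as a set of circular molecules
(a *conformation*). The deposited assembly is the single-circle master
conformation; alternative conformations arise by homologous recombination
between the two copies of a repeat pair. The algebra implemented in
`mitoforms.conformations` has three modes, dictated by the located
geometry of the pair:

* direct copies on one circle → **fission** into two circles of sizes
  s₂−s₁ and L−(s₂−s₁) (start-to-start distances, so pairs whose copies
  differ in length — e.g. a gapped 253 bp alignment spanning 244 and
  249 bp of sequence — have well-defined product sizes);
* direct copies on two circles → **fusion** into one circle of summed
  length;
* inverted copies on one circle → **inversion** of the intervening
  segment.

The crossover is placed at the repeat midpoint. Product *sizes* are
independent of the crossover position; fixing it makes product *sequences*
deterministic, and makes fission and fusion exact inverses (the midpoint
of a product's hybrid copy is the midpoint at which it was formed).
Inverted copies on two distinct circles admit no circular product and are
rejected.

Conformation identity is the sorted multiset of canonical circle
sequences, where the canonical form of a circle is the lexicographically
least string over all rotations of itself and of its reverse complement
(Booth's least-rotation algorithm on both strands). This makes state
deduplication exact under rotation and strand flip, so breadth-first
enumeration of reachable conformations terminates; with three co-resident
direct pairs the closure is the 8-element subset lattice (one state per
repeat subset), of which an analysis would typically draw the handful of
states whose products it observed.

Repeat copies are located on a conformation by near-exact search (edlib,
tolerance 15% of copy length, both strands, doubled sequence for origin
wrap) of the stored copy sequences rather than by coordinate bookkeeping —
necessary because recombination replaces the original copies with
midpoint hybrids. A pair found at more (or fewer) than two distinct
locations raises an ambiguity (or location) error rather than guessing.

## Repeat discovery

**Microsatellites.** Perfect tandem repeats of 1–6 bp motifs under
MISA-style minimum counts (`{1:10, 2:6, 3:5, 4:5, 5:5, 6:5}`). A run is
reported once, at its shortest period, at its leftmost phase, counted in
whole motif units. SSRs separated by ≤ 100 bp (the conventional MISA
interruption distance) share a compound tag but are not merged, so plain
counts stay comparable. The scanner is validated against an independent
backreference-regex oracle.

**Dispersed repeats.** Maximal exact repeated pairs of length ≥ 30 bp
(configurable; "web default"-style) in the four REPuter categories
(forward, palindromic, reverse, complement), found by k-mer seeding with
maximal extension and validated against an exhaustive diagonal-scan
oracle. Copies must not overlap (this excludes tandem-internal shifts);
each unordered pair is reported once. The scan is linear-sequence, as in
REPuter; approximate (Hamming-distance) repeats are out of scope, so
mismatch-tolerant counts from such tools are not expected to reproduce
exactly.

**Paired repeats.** BLAST-like local self-alignment of the circle:
exact-word seeding (word size 11), ungapped X-drop extension, diagonal
clustering, then banded Smith–Waterman refinement
(Bio.Align.PairwiseAligner; match +2, mismatch −3, affine gap 5 + 2g) and
a Karlin–Altschul e-value E = K·m·n·e^(−λS) with K = 0.41, λ = 0.625 and
m = n = L. The circle is compared against its doubled self so copies
spanning the origin are found; the trivial self-diagonal is masked and
overlapping candidates for the same locus pair are pruned greedily by
score. The e-value model is BLASTN-like but not bit-compatible with NCBI
constants, so the threshold (default 10⁻⁵) is a significance knob, and
absolute pair counts from other tools are not a comparison target.

## Long-read spanning evidence

For a repeat pair, four templates are built from the circle: each copy
with 1000 bp flanks (`ref1`, `ref2`), and the two recombinants obtained by
exchanging downstream flanks (`rec1 = up₁·R₁·down₂`,
`rec2 = up₂·R₂·down₁`). Flanks are taken on the circle; when the arc
between the copies is shorter than requested the flank truncates to the
arc and the truncation is recorded. For inverted pairs the second copy's
frame is its aligned orientation, so "upstream/downstream" swap and
complement consistently.

A read supports a template when it spans the template's discriminating
window — repeat ± 100 bp anchor — at identity ≥ 0.70. Operationally the
window is aligned into the read with edlib (semi-global, both strands)
and three checks are applied to the alignment:

1. the window must be covered end to end: after trimming the alignment to
   its maximal-scoring segment (match +2, mismatch 0, gaps −5 −2/bp — the
   trim a local aligner would perform), no window base may fall outside
   it. This rejects reads that stop inside the window, whose uncovered
   bases a distance-minimizing aligner otherwise disguises as scattered
   insertions;
2. each region — left anchor, repeat, right anchor — must align at
   identity ≥ 0.70 *separately*, so a long well-matching repeat cannot
   subsidize a flank that belongs to a different arrangement;
3. the read is assigned only to its unique best template (edit-distance
   margin ≥ 1); ties are discarded, so reference templates cannot absorb
   recombinant evidence when copies are near-identical.

With error-free reads these rules coincide exactly with substring
containment of the window, which is the oracle the tests use. A pair's
recombination is *supported* when ≥ 2 reads back either recombinant
template (defaulting above 1 guards against single chimeric reads).

## RNA editing

Reads are aligned to coding sequences (internal edlib mapper choosing the
best gene/strand, identity floor 0.75, or SAM via pysam); antisense
alignments are complemented so counts are transcript-space, and bases
within ±2 bp of a read indel are excluded. A site is called when depth is
strictly greater than 10 (a 10× column is not called), and the modal
non-reference base reaches ≥ 3 reads and ≥ 5% of the column — the depth
rule is the conventional filter for this analysis; the count/fraction
guards are this package's defence against sequencing error and are
exposed as flags.
Efficiency is edited/(edited + reference), ignoring third alleles (a
second above-threshold allele flags the site multiallelic). Types are the
12 ordered substitutions with DNA T written U; sites in codon 1 carry a
start-codon flag (the ACG-initiation question) and nothing more. Shares
are rounded to 0.1%, so the sum over populated types can deviate from
100 by up to ±0.6.

## DNA transfer

The same seed-and-extend aligner with word size 7 and E ≤ 10⁻⁶, both
strands, mitogenome vs plastome in deposited orientation. The genome
share merges overlapping mitochondrial intervals before summing
(the unmerged sum is reported alongside); the percentage truncates at
0.01 to match how such shares are conventionally printed (19,887 bp of
270,304 bp → 7.35%).

## Synthetic data

The generator emulates the sweet potato mitogenome system: a 270,304 bp
circle at 44.08% GC; long-read lengths lognormal with 10 kb mean (the gTube
fragmenting target) and nanopore-like error rates (substitution 0.05,
insertion 0.025, deletion 0.025, constant Q in FASTQ); RNA-seq reads of
100 bp at uniform coverage with planted edits carried per-read at the
site's efficiency. Repeat copies are planted by copying a background
segment and scattering point substitutions to the requested identity;
plastid tracts are inserted (not overwritten), growing the genome.
Everything is driven by `numpy.random.default_rng` (PCG64) from one seed
and is byte-reproducible; every manifest suffices to compute expected
downstream outputs without re-reading sequences.

What the generator does **not** emulate: chimeric/adapter artefacts,
quality-score structure, indel repeats in homopolymers, transcript-level
linkage of editing sites (edits are drawn independently per read), and
sequence composition beyond i.i.d. bases at fixed GC. Passing tests
therefore demonstrate correctness of the algorithms under clean
generative conditions, not robustness to every artefact of real
sequencing runs; absolute catalogue sizes on real data (total repeat
pairs, dispersed-repeat counts, editing-site counts, transfer-fragment
counts) are mapper- and threshold-sensitive and are deliberately not
asserted.

## Numerical and design choices

* Coordinates are 1-based inclusive in all I/O, 0-based half-open
  internally; origin-wrapping intervals use start > end, never negative
  positions. Non-ACGT characters normalize to N, and N never matches
  anywhere.
* Gap scores follow the BLAST existence/extension convention (a gap of
  length g costs 5 + 2g).
* Degenerate inputs fail loudly: empty sequences, coordinates off the
  circle, overlapping repeat copies, inverted copies on two circles, and
  unlocatable or ambiguous repeat pairs all raise typed errors.
* Tie-breaks are deterministic everywhere: candidate pairs sort by score
  then leftmost coordinate; enumeration applies pairs in name order
  breadth-first; equal-distance template assignments discard the read.
* Problem sizes in the test suite and acceptance script are desk-scale by
  design — genomes of 20–270 kb, hundreds to a thousand reads, 35 genes —
  chosen so the full synthetic pipeline runs in minutes on one CPU while
  still exercising every code path at the coordinates and rates of the
  sweet potato system the package models.

## Known limitations

Linear and branched genome isoforms are out of scope, as are stoichiometry
estimation of coexisting conformations, recombination-frequency
estimation from support ratios, primer design, genome assembly and
annotation, and phylogenetics. The paired-repeat e-value is calibrated
for ranking and thresholding within this package, not for cross-tool
comparison of absolute counts.
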