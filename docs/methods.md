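# Methods

This note documents the statistical model, the numerical conventions and
the deliberate design choices behind `kmerdisco`, in the order the
pipeline runs.

## k-mer encoding and stores

A k-mer over {A, C, G, T} is a base-4 integer (A=0, C=1, G=2, T=3, first
base most significant), so numeric order equals lexicographic order and
the space is [0, 4^k). k is capped at 31 so codes fit in 62 bits of a
uint64. Windows containing any other character (N, IUPAC codes) are
skipped; lowercase is upcased. Counting is strand-aware by default —
counts are taken as read, which assumes the library was orientation-
normalized upstream (mates reverse-complemented if stranded); a
`--canonical` switch instead counts min(code, revcomp code) for
unstranded protocols.

The on-disk store is little-endian: header `KSTR1`, u8 k, u8 p, u64 n;
then (u64 prefix, u64 first-record-index) pairs; then (u64 suffix,
u32 count) records. The prefix length p = round(½log₂t − ½log₂log₂t) is
rounded half-up and clamped to [1, k−1]; for t < 4 the formula is
degenerate and p = 1. Counts saturate at 2³²−1 (flagged by the types,
irrelevant at the scales this tool targets). Round-trips are bit-exact,
which the tests verify byte-for-byte.

## Streamed matrix

The matrix exists only as an iterator: a k-way heap merge over the
per-sample sorted stores yields each k-mer present in at least one
sample, with zeros for the others, reading every store sequentially
once through a bounded buffer. Output is provably independent of the
buffer size (tested); the buffer length per sample is
floor(1000 · RAM/(0.011 · N · T)) records, where 0.011 GiB is the
budget ascribed to 1000 buffered k-mers, RAM comes from the
`KMERDISCO_MAX_MEM_GB` environment variable (default 4), N is the
sample count and T the worker count.

Normalization is N_ij = C_ij · RF / T_j with RF = 10⁹; per sample the
normalized column sums to RF exactly (up to float rounding), a
conservation law the acceptance suite asserts at 10⁻⁶ relative
tolerance. Worker t starts at K_t = (4^k − 1)/T · t **evaluated in
double precision and rounded to nearest**: for k = 31, T = 2 this gives
2 305 843 009 213 693 952 = 4³¹/2 (the float64 result), not the integer
floor of (4³¹−1)/2 — the convention is chosen to reproduce that
canonical worked split. The final partition closes at 4^k.

## Reduction

Each row is scored per unordered group pair by a one-dimensional
Gaussian naive-Bayes classifier under Monte Carlo cross-validation:

* split sizes: n_test = round(n_min · p_test) (round half-up),
  n_train = n_min − n_test, both groups subsampled to the smaller
  group's size so priors are genuinely equal;
* model: per-class mean and ML variance of the training counts with a
  variance floor of 1e-9·(pooled variance + 1) so that degenerate
  zero-variance classes never error;
* prediction: argmax of the class log-likelihood (equal priors); the
  per-iteration accuracy is correct/(2·n_test)·100;
* stopping: iterations end early once the running standard error
  (sample standard deviation / √m) of the per-iteration accuracies
  falls below the break threshold (default 0.5), checked from iteration
  10 onward. All candidate iterations are drawn and scored in one
  vectorized pass and the sequential stopping rule is applied to the
  resulting series, which reproduces iteration-by-iteration breaking
  exactly while keeping the per-row cost a handful of array operations.

Group order within a pair is canonicalized, so the score cannot depend
on how the pair is written. Randomness derives from
SeedSequence([master_seed, code]) per k-mer, making results reproducible
and invariant to the number of workers — a property the tests assert by
comparing 1-worker and 4-worker runs.

A k-mer is retained when its best pairwise accuracy reaches the
threshold a (default 65 %). The entropy gate in front of the classifier
discards rows whose count-distribution Shannon entropy is strictly
below H_thr. H_thr starts at 0; the minimum entropy H_min over retained
k-mers is tracked, and after more than E_up retentions the threshold is
re-tuned: first assignment H_thr = H_min − 2·a1·H_min, afterwards
H_thr = H_min − a1·H_min if it currently exceeds that value, else
H_thr = H_min + a2·H_min. E_up starts at 30 and grows by 30 per update.
The adjustment pair defaults to a1 = 0.25, a2 = 0.05 (a1 ≫ a2, both
exposed); the gate keeps a k-mer sitting exactly at the threshold.
Workers run independent gate states; since the gate only removes
candidates, the gated retention set is a subset of the ungated one
(asserted on the standard cohort).

On label-permuted (null) data at 20 vs 20 samples, a small percentage
of k-mers still clears a = 65 — rows where the group means differ by
sampling luck — with accuracies hugging the threshold; the test suite
bounds this at 5 % and checks that nothing scores strongly.

## Graphs and sequences

The linking parameter w is interpreted as the **maximum shift** between
consecutive k-mers (overlap ≥ k − w): a literal minimum overlap of one
nucleotide would connect essentially everything for 31-mers. Two
pruning rules run to a fixed point on raw accuracies: a bifurcation
branch consisting of a single terminal node is clipped, and where
bifurcations chain, the branch with the lowest maximum accuracy is
dropped — never the component's best node. Pruning precedes rescaling;
since the rescale is monotone within each pair, single-pair decisions
are unaffected by the order.

Rescaling maps each pairwise comparison affinely onto 0–100 across all
surviving nodes; a degenerate pair (max = min) maps to 100, not 0, so a
lone informative node is never discarded by the sequence threshold.
Extraction is a depth-first traversal from in-degree-0 nodes (any node
if none): at a bifurcation the branch whose first node's rescaled
accuracy vector is nearest (Euclidean; ties to the smaller code) to the
bifurcating node's continues the current sequence, every other branch
starts a new sequence prefixed by up to three preceding k-mers (fewer
near graph boundaries). Visited-edge marking terminates cycles.
Sequences whose best member accuracy is below t (default = a) are
dropped; emitted sequences reconstruct exactly from their members,
re-verified character-by-character in the tests.

## Annotation

Internal coordinates are 0-based half-open; GTF (1-based inclusive) and
SAM (1-based) are converted at the boundary, and reports print 1-based
inclusive spans. Transcripts typed `retained_intron` are excluded when
loading the GTF. Event rules:

* I/D/S CIGAR operations → insertion / deletion / clipping;
* mismatches inside M runs → mutation, **only** when MD or NM evidence
  is present — a bare M cannot distinguish match from mismatch, which
  is a documented limitation, not an error;
* an N gap (or split alignment) whose flanks land on distinct exons of
  one transcript → splice;
* transcript exonic coverage ≥ d (default 0.5), accumulated over all
  graph sequences with merged-interval arithmetic → DE; positive but
  sub-threshold coverage → a generic gene event (any positive overlap
  suffices; the coverage fraction is reported);
* intron coverage ≥ d (same flag) → intron;
* mapped without sense-strand transcript overlap → intergenic
  (antisense-only overlap is intergenic with a note); no usable
  alignment → unmapped; secondary hits, multiple primary loci or
  all-zero mapping quality → multimapped.

Coverage fractions use merged intervals so overlaps are never counted
twice (checked against a per-base boolean-mask oracle). Each event keeps
one representative k-mer: the highest-accuracy candidate among its
supporting sequences' members, ties to the smaller code.

## Feature evaluation

A single decision tree fit on all samples ranks features by impurity
importance; the top 20 with nonzero importance are selected (a tree that
separates the classes with fewer splits yields fewer, with a warning —
the evaluation driver pads with remaining columns so an OOB curve always
exists). Random forests (500 trees, exposed) with bootstrap out-of-bag
scoring are fit on the top n for n = 2…20; 500 trees comfortably ensure
every sample is out-of-bag at least once, which is asserted at run time.
The final forest plus its importance ranking are serialized (joblib) and
reload to bit-identical predictions. A k-fold harness re-runs the whole
reduction → assembly → selection chain on each training fold and scores
the held-out samples by balanced accuracy.

## Synthetic cohorts

The generator emulates a minimal two-group RNA-seq experiment on a toy
genome: one chromosome of spacer-separated genes — single-exon genes
carrying differential expression (fold 6, direction alternating between
groups so library totals stay balanced and relative-abundance
normalization does not turn every k-mer differential) or a central SNV
(group allele frequencies 1 and 0), and three-exon genes expressed as a
full/exon-skipping isoform mixture (skip fractions 0.9 and 0.1).
Default study conditions: 20 samples per group, 10 DE + 5 SNV + 3
splice + 4 null genes of ~300 nt, 100 nt reads at 30× (chosen so the
full pipeline runs in about a minute on one core while leaving every
stage non-trivial amounts of data), substitution error rate 0.001.
Reads start uniformly along transcripts; the per-gene read count is
deterministic, round(depth · transcript length / read length), so all
within-group variation comes from read placement, allele/isoform
sampling and sequencing error. There is no quality model, no fragment-
size model, no PCR duplicates and no positional bias — passing tests
demonstrate the statistics behave as designed, not that real-library
artefacts are handled.

The truth table lists each signal's diagnostic k-mers (DE: all
transcript k-mers; SNV: the k alt-allele windows over the variant;
splice: junction-spanning k-mers of the skipping isoform, excluding
windows that coincide with full-isoform sequence by chance) and a
broader attributable set (ref-allele windows, the skipped exon and the
full isoform's junctions) used when scoring precision. Everything is a
deterministic function of the seed; FASTQ output is byte-identical
across runs (gzip written with a fixed mtime).

A toy spliced aligner (edlib-based, infix alignment against every
isoform transcript and raw genome, projected through exon structures
into N-gapped CIGARs with NM/MD tags) maps assembled sequences back to
the toy genome. It knows the simulation's isoform structures and exists
so the annotation stage is exercisable end-to-end; real sequences
require a real aligner.

## Known limitations

* Counting holds each sample's distinct k-mers in memory; fine for the
  targeted scales, not for billion-k-mer libraries.
* The naive-Bayes score is univariate by construction; k-mers that
  discriminate only jointly are invisible to the reduction.
* Null retention at the default threshold is a small percentage, not
  zero; downstream selection and OOB scoring are the guard against such
  borderline features.
* Mutation calling is only as good as the aligner's MD/NM tags; pslx
  input is not supported.
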