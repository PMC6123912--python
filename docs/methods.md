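# Methods

## Model overview

`trareco` assembles transcripts in three stages: (1) greedy contig growing
with error-aware alignment, (2) junction search and splicing-graph
construction, (3) joint isoform detection and abundance estimation. The
central data structure is the consensus matrix: a 4×*l* base-count matrix
per contig whose per-column majority (the representative) is used for all
further alignment. Because alignment tolerates a normalized Hamming margin
and every absorbed read votes into the matrix, substitution errors are
corrected continuously during assembly rather than in a separate
pre-correction pass, and erroneous reads still contribute coverage depth to
the downstream graph.

## Alignment semantics

A read **r** of length *m* against a representative **s** of length *l*
admits five placements: complete (read inside **s**), partial-left /
partial-right (dovetail overlaps), contained (**s** strictly inside the
read; only possible when *l* < *m*), or none. An overlap of width *n* is
valid when *n* ≥ *O*<sub>th</sub> and its Hamming distance is at most
⌊*n·D*<sub>th</sub>⌋ — the floor is the conservative reading of a
real-valued error budget. Selection rules, all deterministic:

- complete placements are preferred (they have the widest possible overlap,
  *n* = *m*); among them the smallest distance wins, then the smallest
  offset;
- otherwise the widest overlap wins; ties break by smaller distance, then
  the fixed order partial-left < partial-right < contained, then the
  smallest containment offset;
- representative ties in a column resolve by the fixed base order
  A < C < G < T;
- N never matches any base (including N) and contributes no count to a
  consensus matrix;
- alignment itself is strand-agnostic; callers test the read and its
  reverse complement and keep the wider (then lower-distance, then forward)
  result.

The `contained` mode is the mirror of the complete case when the contig is
still shorter than the read; it extends the contig on both sides. The test
suite pins the whole contract against a brute-force scan over every offset
and direction.

Coordinates are 0-based and half-open everywhere.

## Contig growing, combining, filtering

Reads are processed in input order; each is absorbed into the pool contig
with the widest valid overlap (ties: smaller distance, then smaller contig
id) or becomes a new seed. A w-mer index over representatives prefilters
candidates with w = ⌊O_th / (⌊O_th·D_th⌋ + 1)⌋; by pigeonhole, any valid
overlap contains an exact run of that length, so the prefilter is lossless
(property-tested against the exhaustive scan). Reads containing N fall
outside that guarantee and are rare enough to be ignored by the index;
reads shorter than O_th seed unextendable contigs and are later removed by
the length/depth filter.

Post-combining repeats the same merge logic contig-to-contig at the lower
threshold C_th, adding overlapping consensus columns element-wise — the
natural matrix generalization of the read-update rules. A contig merged in
reverse-complement orientation is flipped first (columns reversed, A↔T and
C↔G rows swapped). Finally, contigs that are both shorter than
`min_contig_len` (default 150) and shallower than `min_depth` (default 2)
are dropped as error debris; the conjunction keeps long-but-shallow contigs
from weakly expressed transcripts.

Previously absorbed reads are never re-aligned after a representative
changes, and reads that matched nothing are not retried once the pool has
matured; both are deliberate simplicity/throughput choices and the main
cause of slight abundance underestimation.

## Junction search and graph construction

Junctions are found by aligning each contig's prefix and suffix inside
every other contig (width ≥ J_th within the same distance margin); only the
widest alignment per (pair, side) is kept. Because the greedy stage sends
shared-exon reads to whichever contig covers them completely, the second
isoform's contigs typically end partway into a shared exon — exactly the
shape the prefix/suffix search detects. Junction orientation is recorded;
groups are strand-resolved by BFS over the orientation parities, flipped
contigs are mirrored in place, and junctions are recomputed forward-only.

Oversized groups (> 40 contigs by default) are decomposed by iteratively
invalidating the junction with the smallest overlap (ties: more mismatches,
then lower id) until every component fits.

Segmentation cuts each contig at every junction boundary. Boundaries
interior to one side of a junction's aligned span are mirrored to the other
side until a fixed point, so a cut inside a shared exon propagates to every
copy; boundaries within 2 bp collapse to the one with the larger supporting
overlap (jitter of that size arises from the distance margin). Segments
covered by a junction's two spans are unified into a single node with the
element-wise sum of their profiles, which conserves total per-base coverage
mass (asserted by tests). Edges follow contig left-to-right order;
compaction merges every singly-connected pair (outdeg(u) = indeg(v) = 1,
u ≠ v) until none remains, concatenating profiles so coverage is again
conserved. Compaction is idempotent and the result minimal.

## Isoform detection and abundance estimation

Maximal paths run from in-degree-0 to out-degree-0 nodes. In cyclic graphs
a node may be included twice (a repeat is assumed to occur at most twice);
paths with any node more than twice, or with more than two distinct
repeated nodes, are discarded. Enumeration is depth-first with those caps
applied as (equivalent) pruning rules and aborts with a warning at
`max_paths` (default 10,000).

The estimator solves min ‖y − Ax‖² + λ‖x‖₁ s.t. x ⪰ 0, with y the
per-node mean coverage depth (plain mean; no length weighting) and A the
node-inclusion counts. The solver is cyclic coordinate descent with
non-negative soft-thresholding: deterministic zero initialization, fixed
coordinate order, convergence tolerance 1e−8 on the max coordinate change,
at most 10,000 sweeps. The objective is non-increasing per sweep; tests
verify KKT residuals ≤ 1e−6 and agreement with an independent
quadratic-programming solution to 1e−6 in objective value. λ is a user
parameter in coverage-depth units (default 1.0); increasing it shrinks the
support (ℓ1-norm monotonicity is property-tested). Columns with zero norm
receive zero abundance.

**Paired-end path filter.** Node-depth data alone cannot always identify
isoforms: in the canonical case of two genes sharing one exon (paths a–S–b
and c–S–d plus the chimeric combinations a–S–d and c–S–b), the least-squares
*and* ℓ1 objectives are constant along the family
x(t) = (x₁−t, t, t, x₄−t), so no penalty setting can prefer the true pair.
Mate pairs break the tie: observed mate placements define which node pairs
genuinely co-occur on a transcript, and a path is removed when two of its
nodes lie within the estimated fragment reach of each other along the path
but were never linked by any pair. The reach is the 90th percentile of
observed same-contig mate separations minus the read length (or a user
override); only nodes at least one read length long participate, since a
mate midpoint must plausibly land in both. Single-end data leaves the path
set untouched.

Candidates below L_th (default 200, excluding short non-coding RNAs) or
with estimated depth below CD_th (default 0 = keep all positive paths) are
discarded. RPKM = 10⁹·d / (L·N) with d the estimated depth, L the read
length and N the library read count.

## Synthetic data generator

The generator emulates a fully-annotated simulation experiment at desk
scale. Genes are chains of 3–6 exons of 150–400 bp; the first isoform uses
all exons and further isoforms drop internal exons at random (or, with
probability 1 − `shared_exon_prob`, receive private exon chains). A tandem
repeat (two adjacent copies of an 80 bp unit by default, i.e. longer than
J_th) can be inserted to exercise cyclic graphs. Expression levels are
log-uniform over [2, 200], spanning undetectably rare to abundant.

Reads have uniform start positions and independent per-base substitution
errors; read or fragment orientation is randomized (unstranded library).
Paired-end mode draws Gaussian fragment lengths clipped to
[2·read_len, transcript length]; read counts are Poisson with mean
depth·length/read_len. The truth table records, per transcript, the
expressed coverage (fraction of bases covered) and the sequenced read
count, from which the realized coverage depth follows as
reads·read_len / (length·expressed coverage) — an identity the tests check
exactly.

What the generator does *not* emulate: indels (the assembler's distance is
Hamming-only and indel robustness is not claimed), quality scores, library
preparation and positional biases, intergenic or intronic background, and
PCR duplicates. Passing tests therefore demonstrate correctness of the
algorithms under the substitution-error model, not performance on real
libraries. One realistic artifact *is* present: with uniform fragment
starts, paired-end per-base coverage is higher mid-transcript than near the
ends (plateau ≈ depth·L/(L−F) for fragment length F), which slightly
inflates depth estimates of short internal nodes.

Evaluation aligns candidates to references by exact k-mer seeding plus
Hamming counting on each diagonal — sufficient for substitution-only data —
and reports sensitivity (greedy one-to-one matching by coverage), precision,
and wide-sense sensitivity (many references may match one candidate,
tolerating artificial gene fusion) at 95/90/80% target coverage. The
matcher is validated against an edit-distance oracle.

## Problem sizes and numerical choices

The test suite and the acceptance script run synthetic problems of 2–8
transcripts (0.7–6.3 kb) at depths 2–200 and 0.6–4 k reads per experiment —
sizes at which every stage's behaviour is still fully checkable against
oracles and exact bookkeeping. Determinism is end-to-end: fixed seeds,
ordered data structures, no randomized initialization; two identical runs
produce byte-identical FASTA/TSV output, and the run manifest contains no
timestamps.

## Known limitations

- Greedy growing is input-order dependent; different read orders can give
  different (individually valid) contig pools.
- Isoforms strictly contained in a longer isoform's path (e.g. shorter
  3′ ends) cannot be reported, since candidates are maximal paths.
- Tandem repeats shorter than the read length are usually collapsed or
  phased linearly by the greedy stage; cyclic graphs arise only when the
  repeat-boundary reads seed a separate contig.
- Abundances are mildly underestimated because unalignable reads are
  discarded, and mid-transcript coverage inflation from paired-end geometry
  biases short internal nodes upward.
- No gapped alignment, no quality-score weighting, no scaffolding across
  graphs, no EM reassignment of ambiguous reads.
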