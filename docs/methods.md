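# Methods

This note documents the models, parameter choices and numerical
conventions behind `msatselect`, and what the synthetic-data tests do
and do not establish about real data.

## Coordinates and quality model

All coordinates are 0-based, half-open. Phred scores decode as
*p* = 10^(−Q/10); only Phred+33 input is accepted, and scores above 62
are rejected as probable Phred+64 encoding. An `N` call is treated as
an explicit base-calling failure (*p* = 1.0) regardless of its stated
quality, so any quality window containing an `N` fails every
threshold.

## Quality trimming

The trimmer selects, per read, the largest region passing three nested
conditions on error probabilities: terminal bracket windows, interior
sliding windows, and region-level caps (overall mean and terminal
windows). The two presets are fixed at bracket 10 bp / 0.003, window
10 bp / 0.003, region 0.003 with 0.02 terminal caps (high stringency)
and 10 bp / 0.02, 50 bp / 0.08, region 0.025 with 0.02 (low
stringency). Conventions the published parameter strings leave open:

* The two region-level numbers are read as (global mean-error cap,
  terminal-window cap), the original lucy semantics.
* Windows operate on probabilities, not raw Phred scores.
* When a candidate region is shorter than a configured window length,
  the whole region is evaluated as a single truncated window of its
  actual length; regions at least one window long are covered entirely
  by full-length sliding windows, so no other truncation arises.
* "Largest region" means largest in bases. Ties break by smaller mean
  error, then leftmost start, making trimming fully deterministic.
* `min_len` (default 100 bp post-trim) is this package's own floor —
  two primers plus a 90 bp product need roughly that much usable
  sequence; it is config-exposed.

The implementation scans candidate lengths in descending order with
precomputed prefix sums and per-window pass/fail arrays; the test
suite compares it against a direct exhaustive subinterval oracle.

A note on nesting: the high-stringency region is *not* a subregion of
the low-stringency region for arbitrary quality layouts (a read with a
short very-clean block and a longer merely-decent block elsewhere is a
counterexample). Under the monotone 3′ quality decay that
pyrosequencing reads actually show — and that the generator emulates —
both regions anchor at the 5′ end and nesting holds; the nesting test
therefore runs on decay-profile reads, while oracle equivalence is
checked on unconstrained random quality strings as well.

## Repeat mining

A locus is a maximal perfect tandem array of a primitive 2–6 bp motif
with at least 5 units; partial trailing units are truncated from the
span. Primitivity excludes homopolymers (an "AA" motif reduces to a
mononucleotide run) and non-minimal motifs ("ACAC"). The canonical
motif is the lexicographic minimum over all rotations of the motif and
of its reverse complement. Interrupted or compound repeats are never
merged; overlapping arrays with different primitive motifs are all
reported. When a sequence carries several qualifying loci, the one
with most units (tie: leftmost) becomes the primer target — more units
means more expected length polymorphism.

## Redundancy resolution

Pairwise similarity is exact affine-gap local alignment
(match +1, mismatch −2, gap open −5, gap extend −2; Biopython's
`PairwiseAligner` supplies the DP) in both orientations. Identity is
*matches / alignment columns* (gaps count as columns), computed only
over columns free of masked (repeat) positions, so similarity is
measured along the flanking regions — two unrelated reads sharing an
(AC)ₙ array score no similarity. A hit requires ≥ 80% identity over
≥ 50 unmasked columns.

Classification: single-linkage components of strictly->95% hits with
at least two members are contigs; contig membership is decided first,
then any remaining sequence with a hit in the closed band [80, 95] is
eliminated (multicopy risk; the boundary 95.0 eliminates); the rest
are singletons.

Consensus building reverse-complement-normalizes members against the
longest one, multiple-aligns them with `mafft` (members are > 95%
identical, so any reasonable progressive order gives the same
columns; input order is fixed by sorted ids for determinism), and
accepts a column's modal symbol when it reaches 66% of members — a
modal gap drops the column, a sub-threshold column becomes `N`.

An optional exact k-mer prefilter skips sequence pairs sharing no
flank k-mer in either orientation before the O(n²) alignment pass.
The word size is 12: at 85% identity over a ~200 bp shared segment the
probability of no intact 12-mer is about 1%, whereas a 16-mer filter
would silently drop roughly a tenth of elimination-band pairs. The
filter is off by default at the API level and on in the pipeline
configuration, where the candidate sets make the quadratic scan the
dominant cost.

## Repetitive-element screening

A candidate is excluded when some local alignment against a library
element (either orientation) exceeds 65% identity over at least 90
columns. Two deliberate departures from the redundancy stage:

* **Scoring.** Homology detection near 65% identity needs alignments
  that extend across the whole divergent copy. Under the redundancy
  scoring (+1/−2), whose break-even density is 2/3, the best local
  alignment of a 70%-identity region collapses to short high-identity
  cores and the 65% rule loses meaning (measured flagging of planted
  copies at 30% divergence: 75%). The screen therefore uses
  match +2, mismatch −3, gap open −8, gap extend −3 — break-even
  identity 60% — so alignments span the element copy above the
  threshold and dissolve below it, and measured identity tracks true
  homology. With this scheme, planted copies at ≤ 30% divergence flag
  at ~100% and copies at ≥ 45% divergence at ~3%.
* **Hit length.** The 90-column floor (rather than the redundancy
  stage's 50) suppresses chance dense cores inside highly diverged
  (≈ 55% identity) regions, which would otherwise leak past the
  identity rule at a few tens of columns. Both scoring and floor are
  config-exposed.

Masked repeat spans participate in this comparison — repetitive
elements routinely contain microsatellites, and that association is
exactly what the screen is for. "Homology" is operationalized as
alignment identity, not query coverage.

## Primer design

Candidate enumeration is exhaustive over every (left start, left
length, right start, right length) placement whose product covers the
entire repeat span, using O(1) per-substring thermodynamic evaluation
from prefix sums of nearest-neighbor enthalpies/entropies. Melting
temperatures use the unified nearest-neighbor parameter set with the
matching entropic salt correction at 50 mM monovalent cation and
50 nM oligo (total strand concentration; CT/4 for non-self-
complementary duplexes, CT with the −1.4 cal/(mol·K) symmetry term
for palindromes). The model is strand-symmetric, so right primers are
evaluated on the forward strand and emitted as reverse complements.

Under these conditions a 20-mer at 50% GC melts near 53 °C, so the
57–63 °C window is populated by GC-rich 20-mers and longer moderate-GC
oligos — the enumeration over lengths 18–27 makes the constraint set
satisfiable for most random flanks.

Pair penalty is the sum of each primer's weighted deviations from the
optima: 1 per bp of length from 20, 1 per °C of Tm from 60, 0.01 per
percentage point of GC from 50. Ranking is total and deterministic
(penalty, then leftmost left primer, then shortest product); the
search is branch-and-bound over penalty-sorted candidates and returns
the exact top k (default 3). Consensus `N` positions are allowed
inside the product but never inside a primer. Hairpin/self-dimer
screening is not implemented; this is a documented divergence from
full primer-design suites.

## Two-track pipeline

Track A: low-stringency trim → mine → cluster → *contig consensuses
only* → RE screen → primers. Track B: high-stringency trim → mine →
cluster → *singletons only* → RE screen → primers. The ledger counts
follow the conventional table: per track, sequences after QC, repeat-
bearing candidates (contigs for track A, singletons for track B),
candidates without RE similarity, and candidates with at least one
acceptable primer pair; the total is the plain sum over tracks.
Cross-track duplicates (same underlying locus recovered by both
tracks, detected by > 95% cross-track identity over masked flanks) are
removed from the primer table once, preferring the contig version for
its consensus accuracy; the deduplicated count is reported separately
and the feature can be disabled. Every stage writes its artifact;
rerunning with `resume` reuses demultiplexing and trimming artifacts
and recomputes everything downstream deterministically, giving
byte-identical outputs.

## Synthetic data generator

The generator emulates what the pipeline consumes, not flowgram-level
sequencing. Defaults define the study conditions:

* 2,000 templates of 340–460 bp; 30% carry a planted perfect repeat
  (enriched mode: 60%), motif length distributed 50/25/12/8/5% over
  2–6 bp, unit counts uniform on 5–14; 5% of repeat-free templates
  carry a 4-unit decoy.
* 12% of templates carry a segment (150–300 bp; floored at 100 bp
  when squeezed next to a repeat) copied from a small generated RE
  library and diverged by uniform substitutions at a rate drawn from
  0–50%.
* Coverage: 70% of templates yield one read (singletons), 30% yield
  three (contig formation). Strands are random.
* Reads get an MID prefix, a linear Phred decline from Q40 to Q24 with
  Gaussian jitter (σ = 1.5), substitutions drawn per base at the
  *stated* quality (so reported scores are calibrated by
  construction), and ±1 bp indels at homopolymer runs ≥ 3 at rate
  10⁻³ per run — the dominant pyrosequencing error mode.
* Planted features sit in the central 20–80% of the template, at least
  60 bp from both ends. This keeps ground truth (locus plus primer
  room) inside the region a stringent trim retains on *either* strand,
  so truth-based recovery measures the pipeline's filters rather than
  trim geometry; the decay tail still exercises the trimmer on every
  read. Accidental ≥ 4-unit arrays outside planted spans are scrubbed
  so the truth table is exact.

Everything derives from one seeded generator; a fixed seed gives
byte-identical FASTQ, truth tables and RE library.

What passing tests show — and do not. The generator's errors are
substitution-dominated with idealized calibration, its repeat flanks
are uniform-random (real flanks have composition bias and low-
complexity stretches), its RE library is tiny and its divergence model
is substitution-only. Recovery and exclusion rates measured on it
validate the pipeline's logic and thresholds under controlled truth;
they are not predictions of marker yield or primer conversion rates on
real genomic libraries, which depend on genome repeat content, RE
database coverage for the taxon, and wet-lab factors outside this
package's scope.

## Problem sizes and runtime

The shipped tests compare the repeat miner against a brute-force
enumerator on 1,000 random strings (≤ 500 bp), the trimmer against the
exhaustive subinterval oracle on 500 reads (≤ 200 bp, both presets,
`min_len` 20 so short reads exercise the strict preset), redundancy
verdicts on 200-template sets, the RE screen on 200 planted copies per
divergence bin, primer designability against an independent
Biopython-based enumerator on 50 templates, and the full pipeline on
the default 2,000-template library. The complete suite runs in a few
minutes on one CPU; `scripts/acceptance.py` repeats the full-pipeline
measurement from a seed in about two minutes.
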