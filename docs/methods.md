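# Methods

This note documents the models implemented in `seqlev`, the defaults and
the reasoning behind them, and what the simulations do and do not show.

## The Sequence-Levenshtein distance

A barcode of length *n* is prepended to a read; everything after it is
sample sequence.  Errors are substitutions, insertions and deletions of
single bases.  An indel inside the barcode shifts the barcode/sample
boundary, so the decoder never knows how long the received barcode is.

d_SL(A, B) is defined as the minimum number of unit-cost substitutions,
insertions and deletions turning A into some word A′, followed by exactly
one free operation: truncating A′ to |B|, or elongating A′ with the
missing suffix of B.  Free truncation of A′ is the same as editing a
prefix of A into B (ignore A's unused suffix); free elongation is the
same as editing A into a prefix of B.  Hence, with D the Wagner–Fischer
matrix of A against B,

    d_SL(A, B) = min( min_j D[|A|, j], min_i D[i, |B|] ).

This is the canonical implementation (`seqlev.metrics`); the accelerated
kernels (`seqlev._kernels`) are required to be bit-identical to it and
are tested as such.  All costs are unit costs — the model counts
operations and never weights them.  Probability-weighted costs and affine
gaps are out of scope.

Properties (all enforced by tests):

* symmetry; d_SL ≤ d_L ≤ max(|A|, |B|); d_SL = 0 iff one word is a
  prefix of the other (the empty word is a prefix of everything).
* **Triangle inequality, restricted.**  On arbitrary word triples the
  free truncation can break the triangle inequality: d_SL(TTCCC, GTT) = 1
  and d_SL(GTT, GGTGTGTTAC) = 1, but d_SL(TTCCC, GGTGTGTTAC) = 5 — a
  short middle word truncates against both neighbours.  The inequality
  that error correction actually rests on is the restricted form: for
  codewords c₁, c₂ of equal length n and any read w with |w| ≥ n,
  d_SL(c₁, c₂) ≤ d_SL(c₁, w) + d_SL(c₂, w).  This form is verified on
  10⁴ random triples (lengths 1–12) and is what makes the k-error
  guarantee below sound; the guarantee itself is additionally verified
  exhaustively.

**Guarantee.**  If a code has pairwise d_SL ≥ 2k + 1, then for any
codeword c corrupted by at most k edits and followed by arbitrary sample
sequence, d_SL(c, read) ≤ k (the corrupted barcode is a prefix of the
read, and elongation is free) while every other codeword is at distance
≥ k + 1 (restricted triangle inequality).  Nearest-codeword decoding is
therefore exact.

## Edit scripts and boundary recovery

`sl_traceback` returns one optimal edit script.  Positions are 1-based on
the source word; the free final step is recorded as
truncate/elongate/none.  When several DP boundary cells are optimal the
last-row cell with column index j closest to |A| is preferred (larger j
on ties): among equally good explanations this picks the one with the
fewest net indels.  Along the path, diagonal moves are preferred over
deletions over insertions.

The decoder reports boundary = n + (insertions − deletions) of the
optimal script: the read position where sample sequence starts.  Two
caveats are deliberate:

* When distinct optimal scripts have different indel balances (e.g. a
  deletion of the barcode's last base followed by sample base X is
  indistinguishable from a substitution to X), the tie-break above
  applies and the reported boundary is the most conservative optimal
  one.  The invariant that always holds is
  d_L(codeword, read[:boundary]) = achieved distance.
* Boundary recovery is exact whenever the applied corruption is the
  unique optimal explanation, which is the typical case and includes the
  worked examples in the test suite.

## Chemical filters

Candidates must have GC content within [40%, 60%] **inclusive** (the
bounds exclude "less than 40 / more than 60"), homopolymer runs of at
most 2 (a run of 3 identical bases is rejected), and must not equal their
own reverse complement (possible only for even n; perfect
self-complementary oligos fold back on themselves).  All three rules are
policy-configurable; the defaults above are used for every reference
size.  For n = 8 they leave 14600 of 65536 words (the GC rule alone
leaves C(8,4)·2⁸ = 17920, since only exactly 4 G/C bases satisfy the
bounds at n = 8).  No length-3 word passes the GC rule — relevant for
the no-correction comparison code below.  Melting temperature, hairpin
and cross-dimer screening are out of scope.

## Code construction

`greedy_closure(seed, candidates, dmin, metric)` scans the candidate pool
in lexicographic order (A < C < G < T, the quaternary 0–3 encoding) and
accepts every barcode at distance ≥ dmin to everything already accepted.
The scan is deterministic given its inputs, and any subset of a valid
code is valid.

`evolutionary_search` searches over seeds, with fitness = closure size:

* steady-state EA; tournament selection of size 2; the child replaces
  the current worst individual if at least as fit, so the best result is
  non-decreasing;
* seeds are 2–4 random pool barcodes satisfying the pairwise constraint;
  mutation replaces one seed member with a random pool barcode that
  keeps the seed internally compatible; no crossover;
* the budget is counted in closure evaluations — the dominant cost —
  which makes configured runs hardware-independent and exactly
  reproducible from `rng_seed`.

Defaults: population 24–50, budget a few hundred evaluations.  The
package's acceptance run uses population 24 with 200 evaluations for
Sequence-Levenshtein codes (length 7 and 8) and 2000 evaluations for the
classic Levenshtein length-8 code, sizes the search reaches reliably
within minutes on one CPU.

dmin = 2k + 1 errors correctable under the code's own metric.  In DNA
context the guarantees differ by metric and are stored on each
`BarcodeSet`: Sequence-Levenshtein codes keep k; classic Levenshtein
codes decoded at fixed length need dmin = 4k + 1 (dmin = 5 for one
error, 9 for two); Hamming codes have no indel guarantee at all.

`verify_code` re-checks all O(|C|²) pairs by brute force; correctness
never depends on any caching or kernel shortcut (the threshold kernel is
tested bit-identical to the plain DP).

## Decoding

`sl_decode` compares every codeword against the read prefix of length
n + k.  Any distance ≤ k is provably unchanged by this windowing (a
longer prefix can only add cost; wrong codewords stay at ≥ k + 1), and
it bounds the per-read cost; `window="full"` reproduces whole-read
distances when values beyond k matter.  Acceptance threshold defaults to
k; `max_distance=None` is best-effort mode (accept any unique minimum).
Ambiguous reads are left unassigned unless a seeded generator is
supplied for random tie-breaking — the default demultiplexing policy
routes them to `undetermined`, and the random policy exists to mirror
the simulation studies.

`classic_decode_fixed_length` implements fixed-length decoding of
classic Levenshtein codes, the procedure whose failure modes motivate
d_SL.  It matches at window n first; if no codeword lies within
distance k it tries every alternative window length n − k … n + k, each
codeword scored by its best window, and resolves remaining ties
randomly.  For k = 1 this is literally "try n, then n − 1 and n + 1".
A strictly staged ladder (n, then ±1, then ±2) was considered and
rejected: with two deletions the true codeword only reappears at window
n − 2, and letting near-miss windows pre-empt it inflates the two-error
failure rate well above the adverse-base level (1/4)² that fixed-length
decoding actually suffers; the pooled fallback reproduces that level.

`hamming_decode` matches read[:n] by Hamming distance (boundary always
n); with `max_distance=0` it degenerates to exact matching, which serves
as the "no correction" baseline.

## Mutation models

* `mutate_exact(word, e)` applies exactly e sequential edits; each draws
  its type uniformly from the allowed set (default substitution /
  insertion / deletion; positions uniform on the current word; inserted
  bases uniform over ACGT).  Substitutions always change the base (drawn
  from the 3 alternatives): the adverse-base failure levels 1/4 and 1/16
  refer to genuine edits, which a silent "substitution" would dilute.
* `mutate_per_base(word, p)` mutates each original base independently
  with probability p — substitution, deletion, or insertion of a uniform
  base in front of it, equally likely.  Inserted bases are not
  re-mutated, so the expected edit count is exactly p·n (verified to
  within binomial error in tests).
* `enumerate_corruptions(word, e)` is the complete ≤ e-edit ball
  (including the unchanged word), built by iterating the single-edit
  neighbourhood with deduplication.

## Simulation studies

**Study 1 — classic codes fail in DNA context.**  Codewords of classic
Levenshtein codes (dmin = 3 and dmin = 5) are embedded in random reads
and corrupted with one (resp. two) random indels; fixed-length decoding
with random tie-breaks is scored against the true codeword.  Indels only:
substitutions do not shift the boundary and are always corrected by
these codes, so including them would only dilute the failure rate the
study is about.  Defaults: barcode length 9 — the length this package
pairs with dmin = 5 classic codes in the six-code comparison, and one at
which both code sizes are non-trivial — read length n + 6, 10⁵ trials
(binomial SE ≈ 0.14 points at the ~25% level).  Expected outcome: the
dmin = 3 code fails in about a quarter of single-indel trials (the
probability that the base sliding into the window is the adverse one);
the dmin = 5 code never fails a single indel and loses about (1/4)² of
two-indel trials.  Observed rates vary by a point or two with the code's
length and density.

**Study 2 — the guarantee, exhaustively.**  For every codeword of a
Sequence-Levenshtein code, every corruption of ≤ k edits, and every
possible context filling the n + k decode window, decoding must return
the original codeword uniquely.  This is a complete enumeration (≈ 45 000
decodes for the length-8 k = 1 code), not a sample; zero failures is the
only passing outcome, and a deliberately under-spaced code is used as a
positive control that failures are detectable.  For large/long codes the
codeword set and the context set can be randomly subsampled (the
corruption enumeration itself is never reduced); the length-12 k = 2
demonstration additionally builds its code over a random 120 000-word
subsample of the 3.7 M filtered candidates, which yields a smaller but
equally valid code.

**Study 3 — many errors, best-effort decoding.**  Every base of the
barcode mutates independently with probability p; the read is then
decoded best-effort (nearest codeword, any distance, random ties).  The
sample suffix is clean: it is redrawn uniformly at random every trial,
which already realises the worst-case context channel, and per-base
errors in the sample would only re-randomise it.  Reads are filled to
length m = n + 6 (configurable; the worked examples use m = 10 with
n = 4), with extra random bases appended in the rare trials where heavy
deletion leaves the read shorter than the largest decoder window — a
real read's sample sequence continues indefinitely.  The six-code
48-barcode comparison uses the smallest adequate codes: classic
Levenshtein dmin 3 / n 6 and dmin 5 / n 9, Sequence-Levenshtein dmin 3 /
n 7 and dmin 5 / n 11, a Hamming dmin 3 / n 5 linear code, and an
exact-match length-3 code.  The last one cannot satisfy the GC filter
(no length-3 word can), so it — and the linear code if the filtered pool
is too small — is drawn from the unfiltered pool.  Expected orderings,
asserted within 3 binomial SE at 10⁴ trials per cell: success decreases
with p; Sequence-Levenshtein beats classic at equal dmin (and at matched
length and dmin); dmin 5 beats dmin 3 within each metric; every
error-correcting code beats the no-correction baseline.  Absolute curve
values are not reproduced — only orderings — since they depend on the
exact code geometry.

## What the synthetic data does not model

The generator draws codewords uniformly, applies the uniform-mix error
channel, and appends uniform random sample sequence.  Real data differ:
error rates are platform- and position-dependent (homopolymer-biased
indels, end-of-read degradation), sample composition is not uniform, and
library artefacts (chimeras, adapter read-through) exist.  Passing tests
therefore demonstrate the combinatorial guarantees and the relative
robustness of the code families under a neutral channel, not absolute
error rates for any particular instrument.  Quality scores are read and
preserved but never used for weighting.

## Numerical and performance notes

* Kernels: numba-compiled pair DP, a banded threshold decision
  (Ukkonen band of half-width dmin − 1 with early exit) used only for
  ≥/< dmin questions, and an in-kernel greedy scan that checks the
  newest accepted word first (conflicts are lexicographically local;
  the acceptance decision is conjunctive, so order cannot change the
  result).  All three are asserted bit-identical to the pure-Python
  definitions; without numba the same code runs un-jitted.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); every simulation report records its
  seed, and CLI runs write a JSON manifest with parameters and file
  digests.
* Degenerate inputs: empty words are valid for all distances
  (d_SL(ε, w) = 0); GC content and homopolymer runs are undefined for
  the empty word and raise; decoding a read shorter than n − k (SL) or
  n + k (fixed-length) raises a truncated-read error.
* Problem sizes in the shipped test/acceptance runs: code search at
  n = 7/8 with budgets of 200–1000 closure evaluations; study 1 at 10⁵
  trials; study 2 exhaustive at n ≤ 8, subsampled at n = 12; study 3 at
  10⁴ trials per (code, p) cell with p ∈ {0.1, 0.3, 0.5}.

## Known limitations

* The evolutionary search is heuristic; reference-size codes are
  reproducible lower bounds, not proven maxima, and longer budgets find
  slightly larger codes.
* Barcodes are assumed to start at read position 0 (no primer offset,
  no dual indexing, no paired-end consensus).
* The k / k + 1 nested-code construction and probability-weighted
  distances are not implemented.
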