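# Methods

## Problem and definitions

For a dna4 text *T* (alphabet {A,C,G,T}) of length *n* and parameters
*k* (k-mer length) and *e* (mismatch budget), the (k, e)-frequency
assigns every start position *i* ∈ [0, n − k] the number of positions
*j* whose k-mer lies within Hamming distance *e* of *Tᵢ*; the
(k, e)-mappability is 1/F[i].  Counting is exact — no thresholds or
sampling — and F[i] ≥ 1 always holds because a k-mer matches itself.

With several genomes, each genome contributes at most one occurrence per
k-mer, so F[i] ∈ [1, #genomes] counts genomes containing the k-mer
approximately.  Reverse-complement search is off by default (each k-mer
is compared against the forward strand only); when enabled, the k-mer's
reverse complement is searched as well — occurrence counts add in
single-genome mode, and in multi-genome mode a genome counts once if it
contains either orientation.  A k-mer equal to its own reverse
complement is then counted twice at its own position in single-genome
mode; this is deliberate and keeps counts additive.

Edit distance is out of scope; the distance is Hamming throughout.

## Text model

Input FASTA records are uppercased and reduced to dna4.  Non-ACGT
characters follow one of two policies:

* `replace_random` (default, seed 42): every ambiguous base is replaced
  by a uniform random base, reproducibly for a fixed seed.
* `exclude`: ambiguous positions are masked; any k-mer window
  overlapping a mask gets no frequency value, and masked positions are
  encoded as the internal separator symbol so no approximate occurrence
  can overlap them either (they neither match nor mismatch).

Records are concatenated with separator symbols (code 5) between them;
k-mer windows never span a record boundary because a window containing a
separator can never match a dna4 pattern.  All internal coordinates are
0-based and half-open; writers convert at the edge (wiggle is 1-based,
BED stays 0-based half-open).

## Index

The bidirectional FM-index stores the Burrows–Wheeler transforms of the
concatenated text and of its reverse, each terminated by its own unique
sentinel (code 0) so that suffix order equals rotation order and
LF-mapping walks are exact.  Suffix arrays are built by numpy
prefix-doubling (O(n log² n)); rank support is a full per-symbol
cumulative-count table (6 × (n+1) int32), a deliberate memory-for-
simplicity trade at the genome sizes this package targets.  The suffix
array is sampled at text positions divisible by the sampling rate
(default 10); locate walks the LF-mapping to the nearest sample, so any
rate yields identical results.  Indexes persist as a directory of .npy
arrays plus a JSON manifest recording the input files, N-policy and
seed.

## Search schemes

A search (π, L, U) visits the p contiguous pattern pieces in order π
(each new piece adjacent to the block already searched, so the matched
text stays contiguous) under cumulative lower/upper mismatch bounds
checked after each piece.  A scheme is accepted only if the searches'
covered error distributions are *exactly* the p-tuples with sum ≤ e and
pairwise disjoint; together with substitution branches that always
exclude the pattern's own symbol, this guarantees every occurrence is
found exactly once, so range widths can be summed without
deduplication.

Shipped schemes (validated at load time from JSON tables):

* e = 0: single exact search, one piece.
* e = 1: two bidirectional searches over 3 pieces (forward covering
  {000, 001}, backward covering {100, 010}).
* e = 2: the published optimum three-search scheme over 4 pieces.
* e = 3, 4: a fallback family over e + 2 pieces partitioning
  distributions by the first piece carrying an error (forward searches
  with forced-zero prefixes).  Valid and disjoint but not step-optimal;
  only search-step counts, never results, depend on this choice.

Pieces divide the pattern as evenly as possible with the remainder on
the last pieces; tests assert the occurrence set is invariant to this
convention.  Patterns shorter than the scheme's piece count (possible
for very small k) fall back to a single-piece full-backtracking scheme.

## Scan, grouping, skipping

The scan visits each record's valid positions left to right.  Up to
s = compute_s(k, e) consecutive positions form a group; the group's
shared infix T[j+s−1 .. j+k) is searched once with the scheme, then the
group is recursively bisected (left half ⌈s/2⌉ k-mers, extending
leftwards first; right half extending rightwards), each step extending
one character by backtracking within the remaining budget.  At a leaf
the surviving suffix-array ranges belong to exactly one k-mer: single
mode sums their widths; multi-genome mode locates them and collects a
genome bitmask (at most 63 genomes; popcount gives the value).

The group width rule, s = ⌊k·0.7⌋ for e = 0 and
⌊k · clamp(k/100, 0.3, 1.0) · 0.7ᵉ⌋ otherwise, is an empirically derived
compromise: a longer shared infix exploits the scheme search more, a
shorter one shares more work among neighbours.  s is clamped into
[1, k − e + 1] so a full group's infix keeps length ≥ e; groups at
record tails simply shrink.

After a leaf is counted, its 0-mismatch ranges (exactly the exact-match
occurrences, because the zero distribution is covered by exactly one
search) are located and the value is forwarded to those positions, which
the scan then skips.  Forwarding is sound because equal k-mers have
equal frequencies — also across the reverse-complement option, since
count(T_j) + count(rc(T_j)) is the same for equal k-mers.  In the
reverse-complement pass (which scans the reverse-complemented text
against the same index) forwarding is simply disabled.

Both grouping (s = 1) and skipping can be switched off; results are
asserted identical under all four combinations.

## Baseline

The threshold-forwarding heuristic of the earlier mappability tool is
included verbatim as a baseline: scan, search each uncounted k-mer with
e mismatches, and if its occurrence count exceeds a threshold *t*,
forward the count to *all* its approximate occurrences as a
max-lower-bound.  With t = ∞ the forwarding branch is dead and the
output equals the exact frequency (asserted on randomized instances);
with small *t* the baseline overestimates rather unique k-mers that lie
within *e* of a repeat, which the tests witness on a constructed text.
It searches the forward strand only and is defined for a single genome.

## Marker reports

Multi-genome runs retain a per-position genome bitmask.  A position is
*unique* when its k-mer occurs in exactly one genome (its own) and
exactly once overall; *pseudo* when confined to one genome but with ≥ 2
occurrences; *shared* when present in all genomes.  Group separation
marks a position when its k-mer is present in every genome of its own
group and absent from the other.  Because unique k-mers come in
overlapping runs, reports also count *non-adjacent* markers: the
preceding valid position must exist in the same record and not be a
marker of the same kind (the first position of a record therefore never
qualifies — the rule requires a preceding k-mer).  Distance statistics
(mean ± population SD) are over gaps between consecutive marker start
positions within a record.

## Synthetic strain sets

The generator emulates the structure of closely related bacterial
strains: one random ancestor, per-strain point substitutions at a fixed
rate (always to a different base), and optional private segment
insertions recorded as ground truth.  Default validation scale is a few
kb per genome and 2–6 strains, which keeps the full randomized suites in
seconds-to-minutes.  What it does not model: indels other than
whole-segment insertion, recombination, base composition bias,
real repeat families, or chance homology between "private" segments and
the backbone.  Passing tests therefore demonstrate algorithmic
correctness (the engine equals the brute-force definition), not
biological performance of marker discovery on real strains, where
divergence is structured rather than uniform.

Randomized validation instances (also used by `scripts/acceptance.py`)
draw n mostly in [40, 400] with a ~1.5 kb instance every tenth draw,
k ∈ [8, 30], e ∈ {0, 1, 2}, both strands, and single- or multi-genome
mode with 2–3 strains at 2 % divergence; single-genome draws use a
skewed base composition half the time to provoke repeats.  These sizes
were chosen so the brute-force all-pairs oracle (quadratic in the number
of windows, guarded at 20 kb total) stays comfortably fast.

## Numerical and degenerate-input choices

* Frequencies are int64 throughout; the raw binary writer can saturate
  to 8/16/32-bit unsigned on request.  Mappability is float64; no
  tolerance enters any comparison because counts are integers.
* Sequences shorter than k contribute no positions (not an error);
  k − e + 1 < 1 is a parameter error; e is capped at 4 (the largest
  shipped scheme).
* Backtracking tries the matching symbol first, then substitutions in
  alphabet order — a determinism-of-traversal choice that cannot affect
  results.
* Lowercase input is uppercased; soft-masking is ignored.
* Multi-genome mode is limited to 63 genomes by the uint64 presence
  bitmask.

## Known limitations

Single-threaded; the scan is pure Python over numpy rank tables, so
throughput is desk-scale (megabase genomes are feasible, gigabase
genomes are not the target).  The e = 3/4 schemes are valid but not
step-optimal.  CSV occurrence export holds all locations in memory.
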