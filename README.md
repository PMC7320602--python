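# mappability

Exact computation of genome **(k, e)-mappability**: for every position of
one or more genomes, how often does the k-mer starting there occur in the
genome(s) with up to *e* Hamming mismatches?

Mappability quantifies how unique or repetitive each region of a genome
is once sequencing errors and variants are taken into account, which
matters wherever short sequences must identify a locus unambiguously:
read-mapping confidence, CRISPR guide design (off-target uniqueness),
probe and primer selection, and marker-sequence discovery among closely
related bacterial strains.

## The quantity

Given a text *T* of length *n* and its k-mer *Tᵢ* starting at position
*i*, the **(k, e)-frequency** is

> F[i] = |{ j : D(Tᵢ, Tⱼ) ≤ e, 1 ≤ j ≤ n − k + 1 }|

with *D* the Hamming distance, and the **(k, e)-mappability** is its
elementwise reciprocal, M[i] = 1 / F[i].  M[i] = 1 marks a k-mer unique
in the whole text even under *e* mismatches; values near 0 mark repeats.

Across multiple genomes the count changes meaning: each genome
contributes at most 1 per k-mer (presence counting), so F[i] says *in how
many genomes* the k-mer occurs approximately.  A k-mer with multi-genome
frequency 1 that occurs exactly once in its own genome is a candidate
**unique marker** for that strain; a k-mer present in all genomes of one
group and absent from another group separates the groups.

Since the number of strings within distance *e* of a k-mer grows
exponentially in *e*, plain k-mer counting cannot answer this.  The
engine here computes F exactly with three devices layered on a
bidirectional FM-index:

1. **Optimum search schemes** — the k-mer is split into pieces and
   searched under cumulative mismatch bounds (π, L, U) chosen so that all
   error distributions are covered exactly once, which both prunes
   backtracking near the root and lets counts from different searches be
   summed directly.
2. **Adjacent k-mer grouping** — *s* consecutive k-mers share an infix of
   length k − s + 1; the infix is searched once and the group is
   recursively bisected, each half extending its extra shared characters
   with the remaining mismatch budget.  The group width follows
   s = ⌊k·0.7⌋ for e = 0 and s = ⌊k · clamp(k/100, 0.3, 1.0) · 0.7ᵉ⌋
   otherwise.
3. **Redundancy skipping** — after a k-mer is counted, its exact matches
   are located and assigned the same value; the scan skips them.

All three are pure optimizations: the package ships an all-pairs oracle
and ablation switches, and its test suite verifies that results are
bit-identical with and without each device.

## Worked example

`examples/compute_mappability.py` builds a 1 kb random genome, copies a
150 bp block to create a duplication, and computes the (20,1)-mappability:

```
genome length: 1150  valid 20-mers: 1131
unique 20-mers (mappability 1): 861
repeated 20-mers (mappability 0.5): 270
first repeated position: 198
wrote example_mappability.wig / .bed
```

The 270 positions with mappability 0.5 are the two copies of the
duplicated block — about 2 × (150 − 20 + 1) windows, plus a few windows
straddling the copy boundaries whose flanks happen to agree.  Every
other 20-mer is unique even allowing one mismatch.

`examples/find_markers.py` runs the multi-genome mode on four synthetic
strains (shared 4 kb backbone, 1 % divergence, one 150 bp private
insertion each) and tabulates strain-specific 30-mers at e = 2:

```
  strain  unique  pseudo  shared non-adj unique  mean dist
 genome0     189       0    3670              3        1.9
 genome1     173       0    3679              1        1.0
 genome2     222       0    3632              5       12.2
 genome3     205       0    3626              3       19.1

recovery vs ground truth: recall 1.000, precision 0.613
```

Every k-mer window inside a private insertion is recovered as a unique
marker (recall 1.0); the surplus predictions sit at insertion boundaries
and at the strains' point differences.  `examples/separate_groups.py`
shows the two-group variant and `examples/search_scheme_demo.py` prints
the shipped search schemes and the error distributions each search
covers.

## Command line

The same pipeline is exposed as a two-step tool:

```bash
mappability index --fasta strainA.fa --fasta strainB.fa --index-dir idx
mappability map -K 30 -E 2 --index-dir idx --output-prefix out -t -w -b
```

`index` persists the FM-index of the genome collection; `map` computes
the (K,E)-mappability and writes any of plain text (`-t`), fixedStep
wiggle + chrom.sizes (`-w`), BED5 (`-b`), CSV occurrence locations
(`-d`), and raw little-endian binary (`-r`).  `--multi-genome` switches
to presence counting, `--reverse-complement` also searches each k-mer's
reverse complement, `--frequency` emits counts instead of reciprocals.

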