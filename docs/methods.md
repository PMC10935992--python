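# Methods

## Problem and notation

Given a collection C = {S₁, …, S_m} of strings over an ordered alphabet Σ and
a reference R, compute the generalized suffix array GSA of C: GSA[i] = (d, j)
iff S_d[j..] is the i-th smallest suffix of the collection, ties on content
broken by the document index d. Every document ends in the end-of-string
symbol `$`, shared by all documents and smaller than every Σ-symbol; the
reference ends in `#`, smaller than `$`. All positions and suffix-array
indices in the public API are 1-based and intervals are inclusive. Symbols
are ranked `#` → 0, `$` → 1, Σ-symbols from 2 upward by code point; ranks
only need to be order-preserving, not dense.

The method is designed for collections whose documents are highly similar to
R (e.g. resequenced genomes). Its working set is proportional to the number
of "insert-heads" (below), which for realistic similarity is roughly two
orders of magnitude below the input size.

## Matching statistics and their compressed form

MS[i] = (pᵢ, ℓᵢ) records the longest prefix (the *matching factor* U) of
S[i..] that occurs in R, via its length ℓᵢ and one occurrence pᵢ (pᵢ = −1 when
U is empty, which after reference augmentation happens only at the sentinel).
Since a factor of length ℓ at i implies one of length ℓ−1 at i+1, the length
sequence is a concatenation of decrement runs; positions breaking a run
(ℓⱼ > ℓⱼ₋₁ − 1) are *heads*, and storing (j, MS[j]) only at heads with a
predecessor structure reconstructs any MS[i] = (pⱼ+k, ℓⱼ−k), k = i − j.

The enhanced entry ems(i) = (qᵢ, ℓᵢ, xᵢ, cᵢ) replaces pᵢ by qᵢ = SA_R[ip(i)],
where the *insert point* ip(i) is the rank of the largest U-prefixed R-suffix
below U·cᵢ when one exists, else the smallest rank of the U-interval (and 1
for empty U); cᵢ is the mismatch character and xᵢ says whether U·cᵢ falls
below (S) or above (L) R[qᵢ..]. *Insert-heads* are the positions where q
breaks its own increment run (qⱼ ≠ qⱼ₋₁ + 1); every head is an insert-head.
The eCMS stores (j, ems(j)) at insert-heads; reconstruction mirrors the CMS
and recovers ip(i) with a single inverse-suffix-array lookup ISA_R[qⱼ+k].

### Computing the scan

The per-document scan is left-to-right. The factor interval of position i+1
is obtained from that of i by one *left contraction* — map both interval ends
through SA/ISA (s′ = ISA[SA[s]+1], e′ = ISA[SA[e]+1]) and expand with
threshold PSV/NSV queries on the LCP array, SA[PSV(LCP, s′, ℓ−1) ..
NSV(LCP, e′+1, ℓ−1) − 1] — followed by *right extensions* (two binary
searches per character) until the extension is empty. The failed extension's
insertion rank yields ip and x for free.

The *leaf-branch fast path*: when the previous factor is long relative to the
repetitiveness of R, the contracted interval is a singleton and the PSV/NSV
expansion can be skipped. The package takes the fast path only when ℓᵢ − 1
strictly exceeds the blockwise LCP maxima of the block(s) covering ranks
ISA[pᵢ+1] and ISA[pᵢ+1]+1 — a sufficient condition for both boundary LCP
entries of the contracted interval to be below ℓᵢ − 1, so the fast path is
exact by construction (and tested to be bit-identical to the slow path).

### Choice of pᵢ

pᵢ is deterministic: at heads it is the suffix-array-leftmost occurrence of
the final factor interval; inside a decrement run it continues as pᵢ₋₁ + 1.
This is the unique choice consistent with head-based reconstruction, so the
direct stream and the store round-trip are identical arrays.

## Comparing suffixes

With insert points in hand, suffix comparison is largely order arithmetic:

* different insert points — the smaller ip wins outright;
* equal ip — an S-flagged suffix precedes any L-flagged one; within S shorter
  factors come first, within L longer factors come first; equal (ℓ, x) falls
  back to the mismatch character;
* full tie (all of ip, ℓ, x, c equal) — the suffixes share U·c, i.e. ℓ+1
  symbols.

Tie resolution distinguishes two cases. If c = `$`, both suffixes are exactly
U·$ — identical content — and the document index decides. Otherwise an
insert-head provably exists within (i, i+ℓ] on both sides and the *first*
insert-head after i sits at the same offset in both documents; hopping there
stays inside the shared prefix and preserves the comparison. `compare_full`
iterates this until resolution (the iteration count is asserted against the
total insert-head budget); `compare_with_ranks` replaces the iteration by a
single lookup in a precomputed total order of insert-heads, giving one
ems comparison plus one successor query per side.

A note on the hop target: hopping instead to the last insert-head at or
before the mismatch position i+ℓ looks equivalent but is not — insert-heads
at the boundary offset need not align across documents (a small two-document
counterexample exists, found by randomized testing), and the q-increment run
can even flow through the sentinel leaving no insert-head after i at all.
The first-insert-head hop avoids both pitfalls and is precisely the
recursion realized by the metacharacter string below, which keeps the two
code paths consistent by construction. Both are cross-checked against direct
string comparison on randomized instances.

## The six phases

1. **Reference index.** R is augmented: for each collection symbol missing
   from R, a run of it (as long as its longest run in C) is inserted
   immediately before the terminal `#` — this keeps every non-sentinel ℓ
   positive and the insert point well defined. SA is built by prefix
   doubling (numpy lexsort; O(n log n), self-contained, also used for the
   integer metastring); LCP by the Φ/PLCP method (PLCP is an intermediate
   only); blockwise LCP maxima cap the block-max array at 4096 entries by
   default so it stays cache-resident.
2. **eCMS.** One scan per document; no state crosses a `$` boundary.
3. **Types and buckets.** One back-to-front scan per document classifies
   S/L/S* (the sentinel is S-type; it is S* whenever the document is longer
   than one symbol). S*-suffixes are bucketed by insert point via eCMS random
   access; buckets in increasing ip are globally ordered, and ip = 1 holds
   exactly the sentinels.
4. **Total order of insert-heads.** All insert-heads are partially sorted by
   the composite key (ip, x with S first, ℓ ascending within S / descending
   within L, c); identical tuples share a dense rank starting at m. Each
   document is rewritten as its rank sequence in text order plus a
   per-document terminator (document d gets terminator value d−1: terminators
   are mutually ordered by document and below every head rank, mirroring the
   `$` tie rule). Suffix-sorting this integer string assigns each insert-head
   the rank of its metastring suffix — a strict total order that refines the
   partial one and is validated against `compare_full` pair by pair.
5. **Bucket sort.** Each bucket is sorted with `compare_with_ranks`
   (comparison sort, O(|B| log |B|) per bucket).
6. **Induction.** Generalized SAIS induction: sentinels first in document
   order, non-sentinel S* seeds at bucket tails, a left-to-right scan places
   L-type suffixes at bucket heads, a right-to-left scan re-places all S-type
   suffixes from bucket tails. Position 1 of a document is only ever placed.
   The result is checked to be a permutation of all N coordinates.

When no reference is supplied, S₁ is indexed (with `$` swapped for `#` in the
indexed copy) while remaining in the collection; reference suffixes never
appear in the output.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `block_size` | auto (≈ n/4096, min 1) | LCP block length for the block-max array; smaller blocks make the fast-path test sharper but the array larger |
| `sample_rate` | 32 | predecessor sampling rate b_p; query cost O(log(χ′/b_p) + b_p), space one 32-bit gap per stored position plus χ′/b_p samples |
| `fast_path` | on | leaf-branch heuristic; exactness is guaranteed and tested, so this is purely a speed knob |

## Synthetic data

`generate_collection(ref_len, m, rate, seed)` draws a uniform A/C/G/T
reference and m copies each substituted at ⌊rate·ref_len⌋ distinct uniform
positions with a uniformly chosen *different* nucleotide. This emulates the
similarity structure the method targets (point substitutions against a shared
reference) and drives the randomized acceptance sweep at rates 0 to 0.3. It
deliberately omits indels, rearrangements, uneven coverage and real base
composition; passing the sweep therefore demonstrates correctness of the
construction on substitution-only collections of varying similarity, not
performance claims on real genomes. Correctness on arbitrary content is
covered separately by sweeps over independent random strings (small
alphabets, heavy repeats) that exercise the tie machinery much harder than
similar copies do.

## Numerical and degenerate-input choices

* Threshold PSV/NSV are vectorized linear scans; the construction's
  asymptotics at package scale do not warrant a succinct structure.
* The suffix sorter accepts any integer sequence; suffixes that are proper
  prefixes of others sort first (out-of-range padding −1).
* Ties between content-equal suffixes (duplicated documents) resolve by
  document index everywhere — bucket sort, head ranks (via terminators) and
  induction (sentinel seeding order) all implement the same rule.
* Degenerate documents: a single-`$` document is S-type, never S*, and is
  seeded directly by the sentinel pass of the induction.
* Predecessor gaps are stored as 32-bit values; an overflowing gap (only
  possible for documents beyond 4 Gsymbols between stored heads) trips an
  assertion rather than silently wrapping.

## Problem sizes exercised

The test suite and acceptance script run entirely on synthetic and in-memory
data: the 16 bp worked example; 200+ mutated-copy collections with m ≤ 8 and
document length ≤ 200 across six substitution rates; 2 kb five-copy
collections; and thousands of independent random strings up to length ~20
over 2–4 letter alphabets. These sizes were chosen to make brute-force
oracles (full suffix sorts, direct string comparison of all suffix pairs)
exact and cheap; the construction itself has no size-specific code paths.

## Known limitations

* Single-threaded throughout; the phase structure would admit parallelism
  but none is attempted.
* Pure-Python/numpy construction: suitable for methodological work and
  moderate inputs, not a drop-in replacement for C/C++ suffix sorters on
  multi-gigabyte collections.
* Buckets are held in memory; no semi-external variant.
* Input must be plain sequence collections (multi-FASTA); compressed
  representations (VCF, variation graphs) are out of scope.
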