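# msgsa

Generalized suffix array (GSA) construction for collections of highly similar
DNA-like sequences — pangenome-style inputs where every document is a lightly
mutated copy of a reference. The GSA of a collection C = {S₁, …, S_m} lists
all suffix coordinates (d, j) such that S_d[j..] appears in lexicographic
order, with content ties broken by the document index d. It is the workhorse
behind suffix-array and BWT indexes of sequence collections.

Instead of suffix-sorting the concatenation directly, `msgsa` exploits the
similarity of the documents to a reference R through **matching statistics**:
for every position i of a document S, MS[i] = (pᵢ, ℓᵢ) records the longest
prefix of S[i..] occurring in R (its length ℓᵢ and one occurrence pᵢ). Because
ℓ decreases by at most one per step, MS is a concatenation of decrement runs
and can be stored only at the run breaks ("heads"). The **enhanced** form
ems(i) = (qᵢ, ℓᵢ, xᵢ, cᵢ) replaces pᵢ by the occurrence given by the *insert
point* ip(i) — the rank at which S[i..] would slot into the suffix array of R
— plus the mismatch character cᵢ and a side flag xᵢ ∈ {S, L}. Stored at
"insert-heads" with a predecessor structure (the eCMS), it supports random
access to ems(i) at any position and, crucially, lets any two collection
suffixes be compared with a constant number of structure queries.

The construction then runs in six phases: (1) index the (augmented) reference
— suffix array, inverse, LCP, blockwise LCP maxima; (2) compute the eCMS of
every document with right extensions / left contractions and a leaf-branch
fast path; (3) classify suffixes S/L/S* and bucket the S*-suffixes by insert
point; (4) totally order the insert-heads via a partial sort plus an
integer-alphabet metacharacter string; (5) sort each bucket with the
rank-assisted comparator; (6) induce the remaining suffixes SAIS-style.

## Worked example

```python
import msgsa as M

R = M.Sequence.reference("TGATGGCACAGATACT")   # becomes TGATGGCACAGATACT#
S = M.Sequence.document("GATGGCACATTGATGG")    # becomes GATGGCACATTGATGG$
C = M.StringCollection((S,))
idx = M.ReferenceIndex(M.augment_reference(R, C))

for j, ms in M.compute_heads(S, idx):
    print("head", j, "->", (ms.p, ms.ell))
for rec in M.compute_ecms(S, idx):
    print("insert-head", rec.j, "->", (rec.ems.q, rec.ems.ell, rec.ems.x, rec.ems.c))
print(M.build_gsa(C).gsa.entries[:5])
```

prints

```
head 1 -> (2, 9)
head 9 -> (12, 2)
head 11 -> (1, 6)
insert-head 1 -> (2, 9, 'L', 'T')
insert-head 9 -> (3, 2, 'L', 'T')
insert-head 11 -> (1, 6, 'S', '$')
insert-head 16 -> (11, 1, 'S', '$')
insert-head 17 -> (17, 0, 'L', '$')
[(1, 17), (1, 7), (1, 13), (1, 2), (1, 9)]
```

The three heads say that MS of S against R is fully described by the factor
of length 9 at position 1 (occurring at R position 2), the length-2 factor at
position 9, and the length-6 factor at position 11 — every other entry is
reconstructed as (p+k, ℓ−k). The insert-head tuples add where each suffix of
S would slot among R's suffixes; e.g. position 16 carries (q=11, ℓ=1, S, '$'):
the factor "G" followed by end-of-string falls immediately below the R-suffix
starting at position 11. The final line is the start of the GSA: rank 1 is the
sentinel suffix, rank 2 the suffix "ACATTGATGG$" at position 7, and so on.

There is also a CLI:

```sh
msgsa simulate --ref-len 2000 -m 5 --rate 0.01 --seed 1 -o coll.fa --reference-out ref.fa
msgsa build coll.fa -r ref.fa -o gsa.tsv --report report.json
msgsa check coll.fa -r ref.fa      # brute-force verification, small inputs only
msgsa ms coll.fa -r ref.fa         # per-position MS/eCMS dump as TSV
```

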