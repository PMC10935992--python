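"""Six-phase generalized suffix array construction.

Phase 1  build the augmented reference index (SA/ISA/LCP/block maxima);
Phase 2  compute the enhanced compressed matching statistics of every document;
Phase 3  classify suffix types (S/L/S*) and bucket the S*-suffixes by their
         insert point (buckets in insert-point order are globally ordered);
Phase 4  partially sort all insert-heads by (ip, x, ell, c), encode each
         document as a string of partial-sort metacharacters plus a
         document-ordered terminator, and suffix-sort that integer string to
         obtain a total order of the insert-heads;
Phase 5  sort each S* bucket with the rank-assisted comparator;
Phase 6  induce the remaining suffixes SAIS-style (one left-to-right scan for
         L-type, one right-to-left scan for S-type).

The output GSA lists (document, position) pairs for all suffixes of the
collection in lexicographic order, content ties broken by document index.
Reference suffixes are not part of the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cmp_to_key
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cms_store import EcmsStore
from .reference_index import ReferenceIndex, augment_reference
from .sequence import DOC_RANK, Sequence, StringCollection
from .suffix_compare import compare_with_ranks

S_TYPE, L_TYPE, SSTAR_TYPE = 0, 1, 2


@dataclass
class TypeArray:
    """Per-position S/L/S* classification, one int8 array per document
    (1-based, slot 0 padded)."""

    types: Dict[int, np.ndarray]

    def get(self, d: int, i: int) -> int:
        return int(self.types[d][i])

    def is_s(self, d: int, i: int) -> bool:
        return self.types[d][i] != L_TYPE

    def is_sstar(self, d: int, i: int) -> bool:
        return self.types[d][i] == SSTAR_TYPE

    def sstar_count(self) -> int:
        return int(sum((t == SSTAR_TYPE).sum() for t in self.types.values()))


@dataclass(frozen=True)
class Bucket:
    """S*-suffixes sharing an insert point; buckets in increasing ip order are
    globally ordered."""

    ip: int
    q: int
    members: Tuple[Tuple[int, int], ...]


@dataclass(frozen=True)
class MetaString:
    """The integer metacharacter string: per document the partial-sort ranks of
    its insert-heads in text order followed by a per-document terminator, the
    documents concatenated in index order.  ``origin[t]`` is the (d, j)
    coordinate of the insert-head behind symbol t, or None for a terminator."""

    symbols: np.ndarray
    origin: Tuple[Optional[Tuple[int, int]], ...]


@dataclass
class GsaArray:
    """The generalized suffix array: entries[r] = (d, j) of the r-th smallest
    suffix (1-based ranks in the text output; in-memory list is 0-based)."""

    docs: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.docs = np.asarray(self.docs, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @classmethod
    def from_pairs(cls, pairs) -> "GsaArray":
        pairs = list(pairs)
        return cls(np.asarray([d for d, _ in pairs], dtype=np.int64),
                   np.asarray([j for _, j in pairs], dtype=np.int64))

    @property
    def entries(self) -> List[Tuple[int, int]]:
        return list(zip(self.docs.tolist(), self.positions.tolist()))

    def __len__(self) -> int:
        return int(self.docs.size)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GsaArray)
                and np.array_equal(self.docs, other.docs)
                and np.array_equal(self.positions, other.positions))


def classify_types(C: StringCollection) -> TypeArray:
    """One back-to-front scan per document.  The sentinel is S-type (and S*
    whenever the document has length > 1, since its predecessor is L-type)."""
    out: Dict[int, np.ndarray] = {}
    for doc in C.docs:
        n = len(doc)
        r = doc.ranks
        t = np.empty(n + 1, dtype=np.int8)
        t[0] = -1
        t[n] = S_TYPE
        for i in range(n - 1, 0, -1):
            if r[i] < r[i + 1] or (r[i] == r[i + 1] and t[i + 1] != L_TYPE):
                t[i] = S_TYPE
            else:
                t[i] = L_TYPE
        for i in range(2, n + 1):
            if t[i] == S_TYPE and t[i - 1] == L_TYPE:
                t[i] = SSTAR_TYPE
        out[doc.doc_id] = t
    return TypeArray(out)


def bucket_sstar(C: StringCollection, types: TypeArray,
                 store: EcmsStore) -> List[Bucket]:
    """Place every S*-suffix in the bucket of its insert point (via random
    access to the eCMS); buckets emitted in increasing ip."""
    groups: Dict[int, List[Tuple[int, int]]] = {}
    qs: Dict[int, int] = {}
    for doc in C.docs:
        d = doc.doc_id
        t = types.types[d]
        for i in range(1, len(doc) + 1):
            if t[i] == SSTAR_TYPE:
                ems, ip = store.ems_at(d, i)
                groups.setdefault(ip, []).append((d, i))
                qs[ip] = ems.q
    return [Bucket(ip=ip, q=qs[ip], members=tuple(groups[ip]))
            for ip in sorted(groups)]


def partial_sort_heads(store: EcmsStore) -> Dict[Tuple[int, int], int]:
    """Dense partial-sort ranks of all insert-heads across all documents.

    Composite key from the pairwise ordering rules: insert point, then S
    before L, then factor length (ascending within S, descending within L),
    then mismatch character.  Heads with identical (ip, ell, x, c) share a
    rank.  Ranks start at m, leaving 0..m-1 to the per-document terminators.
    """
    m = len(store.doc_ids)
    keyed = []
    for d in store.doc_ids:
        for rec in store.records(d):
            e = rec.ems
            key = (rec.ip, 0 if e.x == "S" else 1,
                   e.ell if e.x == "S" else -e.ell,
                   _crank(e.c))
            keyed.append((key, (d, rec.j)))
    keyed.sort(key=lambda kv: kv[0])
    ranks: Dict[Tuple[int, int], int] = {}
    rank = m - 1
    prev_key = None
    for key, coord in keyed:
        if key != prev_key:
            rank += 1
            prev_key = key
        ranks[coord] = rank
    return ranks


def _crank(c: str) -> int:
    from .sequence import symbol_rank
    return symbol_rank(c)


def build_meta_string(store: EcmsStore,
                      partial: Dict[Tuple[int, int], int]) -> MetaString:
    symbols: List[int] = []
    origin: List[Optional[Tuple[int, int]]] = []
    for d in store.doc_ids:
        for rec in store.records(d):
            symbols.append(partial[(d, rec.j)])
            origin.append((d, rec.j))
        symbols.append(d - 1)  # terminator: below all head ranks, doc-ordered
        origin.append(None)
    return MetaString(np.asarray(symbols, dtype=np.int64), tuple(origin))


def rank_heads(meta: MetaString) -> Dict[Tuple[int, int], int]:
    """Suffix-sort the metacharacter string; each insert-head's final rank is
    the lexicographic rank of the metastring suffix starting at its symbol.
    Terminators are distinct, so head ranks are a strict total order."""
    from .reference_index import _suffix_sort_ints

    order = _suffix_sort_ints(meta.symbols)
    isa = np.empty(order.size, dtype=np.int64)
    isa[order] = np.arange(order.size)
    return {coord: int(isa[t]) for t, coord in enumerate(meta.origin)
            if coord is not None}


def sort_sstar_buckets(buckets: List[Bucket], store: EcmsStore,
                       head_rank: Dict[Tuple[int, int], int]
                       ) -> List[Tuple[int, int]]:
    """Sort each bucket with the rank-assisted comparator and concatenate the
    buckets in insert-point order."""
    out: List[Tuple[int, int]] = []
    for bucket in buckets:
        members = list(bucket.members)
        if len(members) > 1:
            members.sort(key=cmp_to_key(
                lambda a, b: int(compare_with_ranks(a, b, store, head_rank))))
        out.extend(members)
    return out


def induce_gsa(sorted_sstar: List[Tuple[int, int]], C: StringCollection,
               types: TypeArray) -> GsaArray:
    """SAIS-style induction generalized to a collection.

    The sentinel bucket holds all '$'-suffixes up front, in document order.
    Non-sentinel S*-suffixes seed the tails of their first-symbol buckets; a
    left-to-right scan induces L-type suffixes at bucket heads, a right-to-left
    scan re-places all S-type suffixes from bucket tails.  Position 1 of a
    document has no predecessor and is only ever placed, never induced from.
    """
    m, N = C.m, C.N
    max_rank = max(int(doc.ranks[1:].max()) for doc in C.docs)
    counts = np.zeros(max_rank + 2, dtype=np.int64)
    for doc in C.docs:
        counts += np.bincount(doc.ranks[1:], minlength=max_rank + 2)
    starts = np.zeros(max_rank + 2, dtype=np.int64)
    starts[1:] = np.cumsum(counts)[:-1]
    ends = starts + counts  # exclusive

    out_d = np.zeros(N, dtype=np.int64)
    out_j = np.zeros(N, dtype=np.int64)
    filled = np.zeros(N, dtype=bool)

    def place(slot: int, d: int, j: int, allow_overwrite: bool = False):
        assert allow_overwrite or not filled[slot], "slot written twice"
        out_d[slot], out_j[slot] = d, j
        filled[slot] = True

    # sentinel bucket: all '$' suffixes, ordered by document index
    assert int(starts[DOC_RANK]) == 0
    for d in range(1, m + 1):
        place(d - 1, d, len(C.doc(d)))

    # seed non-sentinel S*-suffixes at bucket tails, in reverse sorted order
    tails = ends.copy()
    for d, j in reversed(sorted_sstar):
        if j == len(C.doc(d)):
            continue  # sentinel, already placed
        c = int(C.doc(d).ranks[j])
        tails[c] -= 1
        place(int(tails[c]), d, j)

    ranks_by_doc = {doc.doc_id: doc.ranks for doc in C.docs}
    tarr = types.types

    # induce L-type suffixes, left to right
    heads = starts.copy()
    heads[DOC_RANK] = m
    for r in range(N):
        if not filled[r]:
            continue
        d, j = int(out_d[r]), int(out_j[r])
        if j > 1 and tarr[d][j - 1] == L_TYPE:
            c = int(ranks_by_doc[d][j - 1])
            place(int(heads[c]), d, j - 1)
            heads[c] += 1

    # induce S-type suffixes, right to left (re-places the S* seeds)
    tails = ends.copy()
    for r in range(N - 1, -1, -1):
        assert filled[r], "empty slot reached during S-induction"
        d, j = int(out_d[r]), int(out_j[r])
        if j > 1 and tarr[d][j - 1] != L_TYPE:
            c = int(ranks_by_doc[d][j - 1])
            tails[c] -= 1
            place(int(tails[c]), d, j - 1, allow_overwrite=True)

    assert bool(filled.all()), "induction left empty slots"
    seen = set(zip(out_d.tolist(), out_j.tolist()))
    assert len(seen) == N, "induction produced duplicate coordinates"
    return GsaArray(out_d, out_j)


@dataclass
class GsaResult:
    """Output of the full pipeline: the GSA plus a run report with the phase
    tallies (head/insert-head/S*/bucket counts and structure sizes)."""

    gsa: GsaArray
    report: Dict[str, int] = field(default_factory=dict)


def build_gsa(C: StringCollection, R: Optional[Sequence] = None, *,
              block_size: int = 0, sample_rate: int = 32,
              fast_path: bool = True) -> GsaResult:
    """Run Phases 1-6 and return the GSA of the collection.

    When no reference is given, S_1 serves as the reference (its indexed copy
    ends in '#'; S_1 itself stays in the collection).  Reference suffixes are
    not part of the output.
    """
    if C.m < 1:
        raise ValueError("empty collection")
    if R is None:
        R = Sequence.reference(C.doc(1).core)
    # Phase 1
    R = augment_reference(R, C)
    idx = ReferenceIndex(R, block_size=block_size)
    # Phase 2
    store = EcmsStore.build(C, idx, sample_rate=sample_rate, fast_path=fast_path)
    # Phase 3
    types = classify_types(C)
    buckets = bucket_sstar(C, types, store)
    # Phase 4
    partial = partial_sort_heads(store)
    meta = build_meta_string(store, partial)
    head_rank = rank_heads(meta)
    # Phase 5
    sorted_sstar = sort_sstar_buckets(buckets, store, head_rank)
    # Phase 6
    gsa = induce_gsa(sorted_sstar, C, types)
    report = {
        "m": C.m,
        "N": C.N,
        "sigma": C.sigma,
        "reference_length": idx.n,
        "block_size": idx.block_size,
        "lcpsum": idx.lcpsum(),
        "heads": sum(store.head_count(d) for d in store.doc_ids),
        "insert_heads": sum(store.chi_prime(d) for d in store.doc_ids),
        "sstar_suffixes": types.sstar_count(),
        "buckets": len(buckets),
        "largest_bucket": max((len(b.members) for b in buckets), default=0),
    }
    return GsaResult(gsa=gsa, report=report)
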