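"""Reference-side index: suffix array, LCP, block maxima, threshold PSV/NSV.

All structures live on the (possibly augmented) reference R, which ends in the
sentinel ``#``, the smallest symbol overall.  Arrays are stored with a pad at
slot 0 so that SA, ISA and LCP can be addressed with 1-based indices exactly as
in the public contracts: ``SA[i] = j`` iff the j-th suffix of R is the i-th in
lexicographic order, ``ISA[SA[i]] = i``, ``LCP[1] = 0`` and for i >= 2
``LCP[i] = |lcp(R[SA[i-1]..], R[SA[i]..])|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import REF_SENTINEL, Sequence, StringCollection


def augment_reference(R: Sequence, C: StringCollection) -> Sequence:
    """Insert, for every collection symbol missing from R, a run of that symbol
    (as long as its longest run in the collection) immediately before the
    terminal ``#``.

    Guarantees that every non-sentinel symbol of the collection occurs in R, so
    matching-statistics lengths are positive everywhere except at sentinels and
    the insert point is well defined.  No-op when nothing is missing.
    """
    if R.sentinel != REF_SENTINEL:
        raise ValueError("reference must end in '#'")
    missing = sorted(C.symbols() - set(R.core))
    if not missing:
        return R
    tail = "".join(c * C.longest_run(c) for c in missing)
    return Sequence(R.core + tail + REF_SENTINEL, doc_id=0,
                    original_length=R.original_length)


def _suffix_sort_ints(keys: np.ndarray) -> np.ndarray:
    """0-based suffix array of an arbitrary integer sequence (prefix doubling).

    A suffix that is a proper prefix of another sorts first (out-of-range
    positions are padded with -1, below every symbol).  O(n log n), fully
    vectorised; used both for the reference text and for the integer-alphabet
    metacharacter string.
    """
    keys = np.asarray(keys, dtype=np.int64)
    n = keys.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    order = np.argsort(keys, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    srt = keys[order]
    rank[order] = np.cumsum(np.r_[0, (srt[1:] != srt[:-1]).astype(np.int64)])
    h = 1
    while rank[order[-1]] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - h] = rank[h:]
        order = np.lexsort((second, rank))
        a, b = rank[order], second[order]
        changed = np.r_[0, ((a[1:] != a[:-1]) | (b[1:] != b[:-1])).astype(np.int64)]
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        h *= 2
    return order


def build_suffix_array(R: Sequence) -> np.ndarray:
    """1-based suffix array of R as a padded array (slot 0 unused)."""
    order = _suffix_sort_ints(R.ranks[1:])
    sa = np.empty(order.size + 1, dtype=np.int64)
    sa[0] = 0
    sa[1:] = order + 1
    return sa


def build_inverse(SA: np.ndarray) -> np.ndarray:
    """Inverse permutation (padded, 1-based): ISA[SA[i]] = i."""
    sa = np.asarray(SA)
    n = sa.size - 1
    body = sa[1:]
    if n < 1 or sorted(body.tolist()) != list(range(1, n + 1)):
        raise ValueError("SA is not a permutation of 1..n")
    isa = np.empty(n + 1, dtype=np.int64)
    isa[0] = 0
    isa[body] = np.arange(1, n + 1)
    return isa


def build_lcp(R: Sequence, SA: np.ndarray) -> np.ndarray:
    """LCP array (padded, 1-based) via the Phi/PLCP method.

    PLCP is computed in text order with the standard decrement argument and
    permuted into SA order; it is a construction intermediate only.
    """
    n = len(R)
    if SA.size - 1 != n:
        raise ValueError("SA length does not match sequence")
    isa = build_inverse(SA)
    ranks = R.ranks
    phi = np.zeros(n + 1, dtype=np.int64)
    for i in range(2, n + 1):
        phi[SA[i]] = SA[i - 1]
    plcp = np.zeros(n + 1, dtype=np.int64)
    ell = 0
    for j in range(1, n + 1):
        k = phi[j]
        if k == 0:  # first suffix in SA order
            ell = 0
        else:
            while j + ell <= n and k + ell <= n and ranks[j + ell] == ranks[k + ell]:
                ell += 1
        plcp[j] = ell
        if ell > 0:
            ell -= 1
    lcp = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, n + 1):
        lcp[i] = plcp[SA[i]]
    lcp[1] = 0
    return lcp


def build_block_max(LCP, b: int) -> np.ndarray:
    """Blockwise maxima of an LCP array: M[k] = max of block k (1-based blocks
    of size b; the last block may be short).  ``LCP`` is unpadded here (index 0
    holds LCP[1]), matching the plain-array contract."""
    if b < 1:
        raise ValueError("block size must be >= 1")
    A = np.asarray(LCP, dtype=np.int64)
    n = A.size
    nb = -(-n // b)
    M = np.empty(nb, dtype=np.int64)
    for k in range(nb):
        M[k] = A[k * b : (k + 1) * b].max()
    return M


def psv_threshold(A, i: int, t: int):
    """Greatest i' <= i with A[i'] < t, or None (1-based; plain array)."""
    A = np.asarray(A)
    if not 1 <= i <= A.size:
        raise IndexError(f"index {i} out of range 1..{A.size}")
    hits = np.nonzero(A[:i] < t)[0]
    return int(hits[-1]) + 1 if hits.size else None


def nsv_threshold(A, i: int, t: int):
    """Smallest i' >= i with A[i'] < t, or None.  Querying at i = |A|+1 returns
    |A|+1 (virtual sentinel), so left-contraction's e'+1 argument is always
    legal (1-based; plain array)."""
    A = np.asarray(A)
    n = A.size
    if i == n + 1:
        return n + 1
    if not 1 <= i <= n:
        raise IndexError(f"index {i} out of range 1..{n + 1}")
    hits = np.nonzero(A[i - 1 :] < t)[0]
    return i + int(hits[0]) if hits.size else None


def lcpsum(LCP) -> int:
    """Sum of the LCP array, a repetitiveness measure: the number of distinct
    substrings of T equals (|T|^2+|T|)/2 - LCPsum(T)."""
    return int(np.asarray(LCP, dtype=np.int64).sum())


#: default cap on the size of the block-max array M (entries)
_DEFAULT_M_ENTRIES = 4096


@dataclass
class ReferenceIndex:
    """All reference-side structures used by matching-statistics computation.

    ``block_size`` defaults so that M has at most 4096 entries (16 KiB at 4
    bytes each), keeping it cache-resident on typical hardware.
    """

    seq: Sequence
    block_size: int = 0
    sa: np.ndarray = field(init=False, repr=False)
    isa: np.ndarray = field(init=False, repr=False)
    lcp: np.ndarray = field(init=False, repr=False)
    block_max: np.ndarray = field(init=False, repr=False)
    plcp_used: bool = field(init=False, default=True)

    def __post_init__(self):
        if self.seq.sentinel != REF_SENTINEL:
            raise ValueError("reference must end in '#'")
        n = len(self.seq)
        if self.block_size < 1:
            self.block_size = max(1, -(-n // _DEFAULT_M_ENTRIES))
        self.sa = build_suffix_array(self.seq)
        self.isa = build_inverse(self.sa)
        self.lcp = build_lcp(self.seq, self.sa)
        self.block_max = build_block_max(self.lcp[1:], self.block_size)

    @classmethod
    def build(cls, R: Sequence, C: StringCollection | None = None,
              block_size: int = 0) -> "ReferenceIndex":
        """Augment R against C (when given) and build the index."""
        if C is not None:
            R = augment_reference(R, C)
        return cls(R, block_size=block_size)

    @property
    def n(self) -> int:
        return len(self.seq)

    def psv(self, i: int, t: int):
        """Threshold PSV on this index's LCP array."""
        return psv_threshold(self.lcp[1:], i, t)

    def nsv(self, i: int, t: int):
        """Threshold NSV on this index's LCP array (virtual sentinel at n+1)."""
        return nsv_threshold(self.lcp[1:], i, t)

    def suffix(self, rank: int) -> str:
        """The suffix of R with lexicographic rank ``rank`` (debug helper)."""
        return self.seq.suffix(int(self.sa[rank]))

    def lcpsum(self) -> int:
        return lcpsum(self.lcp[1:])
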