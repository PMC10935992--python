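"""Matching statistics, insert points, heads and insert-heads.

For each position i of a document S, the matching factor U is the longest
prefix of S[i..] occurring in the reference R, recorded as MS[i] = (p_i, l_i)
with p_i an occurrence of U in R (p_i = -1 when U is empty, which happens only
at the sentinel).  The scan proceeds left to right: one left contraction of the
previous factor interval, then right extensions with successive characters of S
until the extension is empty.  The failed extension also yields the insert
point ip(i) — the rank at which S[i..] would slot into SA_R — from which the
enhanced entry ems(i) = (q_i, l_i, x_i, c_i) is derived (q_i = SA_R[ip(i)],
c_i the mismatch character, x_i = S/L telling whether U·c_i falls below or
above R[q_i..]).

Heads are the positions where the length sequence breaks its decrement run
(l_j > l_{j-1} - 1); insert-heads the positions where q breaks its increment
run (q_j != q_{j-1} + 1).  Every head is an insert-head.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

from .reference_index import ReferenceIndex
from .sequence import DOC_RANK, Sequence, symbol_rank


@dataclass(frozen=True)
class MsEntry:
    """One matching-statistics entry: occurrence p (1-based, -1 if empty) and
    factor length ell."""

    p: int
    ell: int


@dataclass(frozen=True)
class EmsEntry:
    """One enhanced entry (q, ell, x, c): insert-point occurrence q = SA_R[ip],
    factor length, side flag x in {'S','L'} and mismatch character c."""

    q: int
    ell: int
    x: str
    c: str


@dataclass(frozen=True)
class SaInterval:
    """Inclusive SA-rank interval [s..e] of the suffixes of R prefixed by a
    factor Y with |Y| = depth."""

    s: int
    e: int
    depth: int

    def __post_init__(self):
        if self.s > self.e:
            raise ValueError("empty interval")


@dataclass(frozen=True)
class EmptyExtension:
    """Result of a failed right extension: the rank where Yc would slot in."""

    insert_rank: int


@dataclass(frozen=True)
class PositionRecord:
    """Full per-position record of the scan (direct, uncompressed view)."""

    i: int
    p: int
    ell: int
    q: int
    ip: int
    x: str
    c: str
    is_head: bool
    is_ihead: bool

    @property
    def ms(self) -> MsEntry:
        return MsEntry(self.p, self.ell)

    @property
    def ems(self) -> EmsEntry:
        return EmsEntry(self.q, self.ell, self.x, self.c)


@dataclass(frozen=True)
class InsertHeadRecord:
    """An insert-head j of document d with its enhanced entry and insert point;
    ``is_head`` marks the subset that are also plain heads."""

    d: int
    j: int
    ems: EmsEntry
    ip: int
    is_head: bool


def _extend_bounds(rr, sa, s: int, e: int, depth: int, c: int) -> Tuple[int, int]:
    """Binary-search bounds of the Yc-interval inside the Y-interval [s..e].

    Returns (lo, hi): the Yc-interval is [lo..hi] when lo <= hi; otherwise the
    extension is empty and lo is the rank at which Yc would be inserted.
    Within a Y-interval every suffix is strictly longer than depth (suffixes of
    R end in '#', which no factor contains), so the character at offset
    ``depth`` always exists.
    """
    lo, hi = s, e + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if rr[sa[mid] + depth] < c:
            lo = mid + 1
        else:
            hi = mid
    first = lo
    lo, hi = first, e + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if rr[sa[mid] + depth] <= c:
            lo = mid + 1
        else:
            hi = mid
    return first, lo - 1


def right_extension(idx: ReferenceIndex, iv: SaInterval, c: str):
    """Compute the Yc-interval from the Y-interval by a pair of binary
    searches; when empty, return the insert rank instead."""
    lo, hi = _extend_bounds(idx.seq.ranks, idx.sa, iv.s, iv.e, iv.depth,
                            symbol_rank(c))
    if lo <= hi:
        return SaInterval(lo, hi, iv.depth + 1)
    return EmptyExtension(insert_rank=lo)


def left_contraction(idx: ReferenceIndex, iv: SaInterval) -> SaInterval:
    """Compute the Y-interval (depth-1) from the cY-interval via
    s' = ISA[SA[s]+1], e' = ISA[SA[e]+1] and the threshold PSV/NSV expansion
    SA[PSV(LCP, s', |Y|) .. NSV(LCP, e'+1, |Y|) - 1]."""
    if iv.depth < 1:
        raise ValueError("cannot contract an interval of depth 0")
    n = idx.n
    if iv.depth == 1:
        return SaInterval(1, n, 0)
    t = iv.depth - 1
    s2 = int(idx.isa[idx.sa[iv.s] + 1])
    e2 = int(idx.isa[idx.sa[iv.e] + 1])
    x = idx.psv(s2, t)
    y = idx.nsv(e2 + 1, t)
    if y is None:
        y = n + 1
    return SaInterval(x, y - 1, t)


def insert_point(idx: ReferenceIndex, iv: Optional[SaInterval], c: str) -> Tuple[int, str]:
    """Insert point and side flag for a matching factor U with mismatch c.

    ``iv`` is the U-interval (None or depth 0 stands for U = empty, in which
    case ip = 1).  ip is the rank of the largest U-prefixed suffix of R below
    U·c when one exists, else the smallest rank of the U-interval; x = 'S' iff
    U·c < R[SA[ip]..].
    """
    if iv is None or iv.depth == 0:
        s, e, depth = 1, idx.n, 0
    else:
        s, e, depth = iv.s, iv.e, iv.depth
    lo, _hi = _extend_bounds(idx.seq.ranks, idx.sa, s, e, depth, symbol_rank(c))
    if lo > s:
        return lo - 1, "L"
    return s, "S"


def _fast_path_ok(idx: ReferenceIndex, j0: int, t: int) -> bool:
    # Singleton contraction needs both boundary LCP entries of the contracted
    # interval below t; block maxima bound them from above.
    b = idx.block_size
    M = idx.block_max
    if M[(j0 - 1) // b] >= t:
        return False
    if j0 < idx.n and M[j0 // b] >= t:
        return False
    return True


def scan_positions(S: Sequence, idx: ReferenceIndex,
                   fast_path: bool = True) -> Iterator[PositionRecord]:
    """Left-to-right scan yielding the full per-position record stream.

    Raises ValueError when a non-sentinel symbol of S does not occur in R
    (the reference was not augmented for this collection).
    """
    n = idx.n
    sa, isa = idx.sa, idx.isa
    rr = idx.seq.ranks
    sr = S.ranks
    m = len(S)
    lcp = idx.lcp

    prev_ell = 0
    prev_p = -1
    prev_q = 0
    s = e = 1
    depth = 0
    for i in range(1, m + 1):
        if i == 1:
            s, e, depth = 1, n, 0
            p_cont = -1
        else:
            t = prev_ell - 1
            p_cont = prev_p + 1 if prev_ell > 0 else -1
            if t <= 0:
                s, e, depth = 1, n, 0
            elif fast_path and _fast_path_ok(idx, int(isa[prev_p + 1]), t):
                s = e = int(isa[prev_p + 1])
                depth = t
            else:
                s2 = int(isa[sa[s] + 1])
                e2 = int(isa[sa[e] + 1])
                x0 = idx.psv(s2, t)
                y0 = idx.nsv(e2 + 1, t)
                if y0 is None:
                    y0 = n + 1
                s, e, depth = x0, y0 - 1, t

        extended = False
        while True:
            c_rank = int(sr[i + depth])
            lo, hi = _extend_bounds(rr, sa, s, e, depth, c_rank)
            if lo > hi:
                break
            s, e, depth = lo, hi, depth + 1
            extended = True

        ell = depth
        c_char = S.char(i + ell)
        if ell == 0:
            if c_rank != DOC_RANK:
                raise ValueError(
                    f"symbol {c_char!r} at position {i} of document "
                    f"{S.doc_id} does not occur in the reference "
                    f"(reference not augmented?)")
            p = -1
        elif extended:
            p = int(sa[s])
        else:
            p = p_cont
        if lo > s:
            ip, x = lo - 1, "L"
        else:
            ip, x = s, "S"
        q = int(sa[ip])
        is_head = i == 1 or ell > prev_ell - 1
        is_ihead = i == 1 or q != prev_q + 1
        yield PositionRecord(i=i, p=p, ell=ell, q=q, ip=ip, x=x, c=c_char,
                             is_head=is_head, is_ihead=is_ihead)
        prev_ell, prev_p, prev_q = ell, p, q


def compute_matching_statistics(S: Sequence, idx: ReferenceIndex,
                                fast_path: bool = True) -> List[MsEntry]:
    """MS[i] for i = 1..|S| (the sentinel yields (-1, 0)).  With the
    leaf-branch fast path on, the output is identical to fast path off."""
    return [rec.ms for rec in scan_positions(S, idx, fast_path=fast_path)]


def compute_ems_stream(S: Sequence, idx: ReferenceIndex,
                       fast_path: bool = True) -> List[PositionRecord]:
    """The uncompressed per-position record stream (testing/debug surface)."""
    return list(scan_positions(S, idx, fast_path=fast_path))


def compute_heads(S: Sequence, idx: ReferenceIndex,
                  fast_path: bool = True) -> List[Tuple[int, MsEntry]]:
    """(j, MS[j]) at each head j — the compressed matching statistics payload."""
    return [(rec.i, rec.ms) for rec in scan_positions(S, idx, fast_path=fast_path)
            if rec.is_head]


def compute_ecms(S: Sequence, idx: ReferenceIndex,
                 fast_path: bool = True) -> List[InsertHeadRecord]:
    """Insert-head records of S in increasing position — the eCMS payload."""
    return [InsertHeadRecord(d=S.doc_id, j=rec.i, ems=rec.ems, ip=rec.ip,
                             is_head=rec.is_head)
            for rec in scan_positions(S, idx, fast_path=fast_path)
            if rec.is_ihead]
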