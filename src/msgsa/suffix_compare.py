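"""Ordering collection suffixes from enhanced matching statistics.

A single ems comparison decides most pairs: a smaller insert point wins
outright; at equal insert points the factor length, the S/L side flag and the
mismatch character decide (shorter with S is smaller, shorter with L is
larger, S before L, then the mismatch characters).  Only fully identical
tuples are left TIE, and a tie is resolved by hopping to the insert-heads
covering the mismatch characters — either recursively on the raw store, or in
one step once a total order of all insert-heads is available.
"""

from __future__ import annotations

import enum
from typing import Dict, Tuple

from .cms_store import EcmsStore
from .matching_statistics import EmsEntry
from .sequence import DOC_SENTINEL, symbol_rank


class Comparison(enum.IntEnum):
    LT = -1
    TIE = 0
    GT = 1


def compare_ems(a: Tuple[int, EmsEntry], b: Tuple[int, EmsEntry]) -> Comparison:
    """Partial-order comparison of two suffixes from (ip, ems) alone.

    TIE iff insert point and all four tuple components coincide; any non-TIE
    outcome agrees with direct lexicographic comparison (the lexicographic
    order refines this relation).
    """
    ip_a, ems_a = a
    ip_b, ems_b = b
    if ip_a != ip_b:
        return Comparison.LT if ip_a < ip_b else Comparison.GT
    # an S-flagged suffix sits below its insert suffix, an L-flagged one above
    if ems_a.x != ems_b.x:
        return Comparison.LT if ems_a.x == "S" else Comparison.GT
    if ems_a.ell != ems_b.ell:
        if ems_a.x == "S":
            return Comparison.LT if ems_a.ell < ems_b.ell else Comparison.GT
        return Comparison.GT if ems_a.ell < ems_b.ell else Comparison.LT
    ca, cb = symbol_rank(ems_a.c), symbol_rank(ems_b.c)
    if ca != cb:
        return Comparison.LT if ca < cb else Comparison.GT
    return Comparison.TIE


def _doc_order(d: int, d2: int) -> Comparison:
    if d == d2:
        return Comparison.TIE
    return Comparison.LT if d < d2 else Comparison.GT


def compare_full(a: Tuple[int, int], b: Tuple[int, int],
                 store: EcmsStore) -> Comparison:
    """Total-order comparison of suffixes (d,i) and (d',i') by iterated tie
    resolution: on TIE, hop to j = i-head(i + ell) in each document (the
    offsets j - i and j' - i' provably agree) and compare again.  Content-equal
    suffixes from different documents resolve by document index; identical
    coordinates compare TIE.
    """
    d, i = a
    d2, i2 = b
    if (d, i) == (d2, i2):
        return Comparison.TIE
    budget = store.chi_prime(d) + store.chi_prime(d2) + 2
    for _ in range(budget):
        ems1, ip1 = store.ems_at(d, i)
        ems2, ip2 = store.ems_at(d2, i2)
        r = compare_ems((ip1, ems1), (ip2, ems2))
        if r != Comparison.TIE:
            return r
        if ems1.c == DOC_SENTINEL:
            # the mismatch character is the end-of-string symbol, so both
            # suffixes are exactly U'$': equal content, document order decides
            return _doc_order(d, d2)
        # the suffixes share U'c (ell+1 symbols); an insert-head exists within
        # (i, i+ell] on both sides, and the first one sits at the same offset,
        # so hopping there preserves the comparison
        j1 = store.next_i_head(d, i)
        j2 = store.next_i_head(d2, i2)
        assert j1 - i == j2 - i2, "tie offsets diverged (broken invariant)"
        i, i2 = j1, j2
    raise AssertionError("tie recursion exceeded the insert-head budget")


def compare_with_ranks(a: Tuple[int, int], b: Tuple[int, int],
                       store: EcmsStore,
                       head_rank: Dict[Tuple[int, int], int]) -> Comparison:
    """Constant-structural-work comparison given the completed total order of
    insert-heads: one ems comparison, then (on TIE) one predecessor lookup per
    side and a rank comparison, with residual ties broken by document index."""
    if head_rank is None:
        raise ValueError("head_rank is required (run the insert-head sort first)")
    d, i = a
    d2, i2 = b
    if (d, i) == (d2, i2):
        return Comparison.TIE
    ems1, ip1 = store.ems_at(d, i)
    ems2, ip2 = store.ems_at(d2, i2)
    r = compare_ems((ip1, ems1), (ip2, ems2))
    if r != Comparison.TIE:
        return r
    if ems1.c == DOC_SENTINEL:
        return _doc_order(d, d2)
    j1 = store.next_i_head(d, i)
    j2 = store.next_i_head(d2, i2)
    assert j1 - i == j2 - i2, "tie offsets diverged (broken invariant)"
    r1, r2 = head_rank[(d, j1)], head_rank[(d2, j2)]
    if r1 != r2:
        return Comparison.LT if r1 < r2 else Comparison.GT
    return _doc_order(d, d2)
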