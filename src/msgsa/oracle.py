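"""Brute-force reference implementations (test-scale oracles).

These deliberately share no code with the production path: the GSA oracle
sorts explicit suffix byte-strings, the matching-statistics oracle searches
the reference text directly.
"""

from __future__ import annotations

from typing import List

from .gsa import GsaArray
from .matching_statistics import MsEntry
from .sequence import Sequence, StringCollection, symbol_rank


def _to_bytes(seq: Sequence) -> bytes:
    # symbol ranks fit a byte for any practical alphabet and preserve order
    return bytes(symbol_rank(c) for c in seq.text)


def naive_gsa(C: StringCollection) -> GsaArray:
    """Sort all (d, j) by (suffix content, document index)."""
    keyed = []
    for doc in C.docs:
        raw = _to_bytes(doc)
        for j in range(1, len(doc) + 1):
            keyed.append((raw[j - 1 :], doc.doc_id, j))
    keyed.sort()
    return GsaArray.from_pairs((d, j) for _, d, j in keyed)


def naive_ms(S: Sequence, R: Sequence) -> List[MsEntry]:
    """Matching statistics by direct substring search: for each i the longest
    prefix of S[i..] occurring in R, with p the leftmost occurrence (p may
    legitimately differ from the production p when the factor repeats; agree
    on length and factor content)."""
    core = R.core
    s = S.text
    out = []
    ell = 0
    for i in range(1, len(S) + 1):
        ell = max(0, ell - 1)  # decrement-run lower bound speeds the scan
        while i + ell <= len(S) and s[i - 1 : i + ell] in core:
            ell += 1
        while ell > 0 and s[i - 1 : i - 1 + ell] not in core:
            ell -= 1
        if ell == 0:
            out.append(MsEntry(-1, 0))
        else:
            out.append(MsEntry(core.find(s[i - 1 : i - 1 + ell]) + 1, ell))
    return out
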