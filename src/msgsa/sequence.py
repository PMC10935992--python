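"""Sentinel-terminated sequences and string collections.

Every document of a collection ends in the end-of-string symbol ``$``; the
reference ends in ``#``.  ``#`` sorts below ``$``, and ``$`` sorts below every
alphabet symbol; all documents share the same ``$`` so that content-equal
suffixes from different documents compare equal (ties are then broken by the
document index).  Positions are 1-based throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REF_SENTINEL = "#"
DOC_SENTINEL = "$"

#: integer rank of the reference sentinel
REF_RANK = 0
#: integer rank of the shared document sentinel
DOC_RANK = 1


def symbol_rank(c: str) -> int:
    """Total order on symbols: ``#`` < ``$`` < all alphabet symbols (by code point)."""
    if c == REF_SENTINEL:
        return REF_RANK
    if c == DOC_SENTINEL:
        return DOC_RANK
    return ord(c) + 2


@dataclass(frozen=True)
class Sequence:
    """A sentinel-terminated string with 1-based indexing.

    Parameters
    ----------
    text
        The full text including the trailing sentinel (``$`` for documents,
        ``#`` for the reference).
    doc_id
        Document index ``d`` (1-based); 0 for a reference.
    original_length
        Length before reference augmentation (equals ``len(text)`` unless the
        sequence was augmented).
    """

    text: str
    doc_id: int = 1
    original_length: int = -1
    # 1-based rank array; slot 0 is a pad and never read
    ranks: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not self.text:
            raise ValueError("empty sequence")
        last = self.text[-1]
        if last not in (REF_SENTINEL, DOC_SENTINEL):
            raise ValueError("sequence must end in a sentinel ('$' or '#')")
        if self.text.count(last) != 1:
            raise ValueError(f"sentinel {last!r} must occur exactly once, at the end")
        other = REF_SENTINEL if last == DOC_SENTINEL else DOC_SENTINEL
        if other in self.text:
            raise ValueError(f"foreign sentinel {other!r} inside sequence")
        r = np.empty(len(self.text) + 1, dtype=np.int64)
        r[0] = -1
        r[1:] = [symbol_rank(c) for c in self.text]
        object.__setattr__(self, "ranks", r)
        if self.original_length < 0:
            object.__setattr__(self, "original_length", len(self.text))

    @classmethod
    def document(cls, core: str, doc_id: int = 1) -> "Sequence":
        """Build a document from its core text (the ``$`` is appended)."""
        return cls(core + DOC_SENTINEL, doc_id=doc_id)

    @classmethod
    def reference(cls, core: str) -> "Sequence":
        """Build a reference from its core text (the ``#`` is appended)."""
        return cls(core + REF_SENTINEL, doc_id=0)

    @property
    def sentinel(self) -> str:
        return self.text[-1]

    @property
    def core(self) -> str:
        """The text without its sentinel."""
        return self.text[:-1]

    def __len__(self) -> int:
        return len(self.text)

    def char(self, i: int) -> str:
        """1-based character access."""
        if not 1 <= i <= len(self.text):
            raise IndexError(f"position {i} out of range 1..{len(self.text)}")
        return self.text[i - 1]

    def suffix(self, i: int) -> str:
        """The suffix ``text[i..]`` (1-based)."""
        if not 1 <= i <= len(self.text):
            raise IndexError(f"position {i} out of range 1..{len(self.text)}")
        return self.text[i - 1 :]


@dataclass(frozen=True)
class StringCollection:
    """An ordered collection of documents S_1..S_m, each ``$``-terminated."""

    docs: tuple

    def __post_init__(self):
        if not self.docs:
            raise ValueError("empty collection")
        fixed = []
        for d, doc in enumerate(self.docs, start=1):
            if doc.sentinel != DOC_SENTINEL:
                raise ValueError(f"document {d} does not end in '$'")
            if doc.doc_id != d:
                doc = Sequence(doc.text, doc_id=d, original_length=doc.original_length)
            fixed.append(doc)
        object.__setattr__(self, "docs", tuple(fixed))

    @classmethod
    def from_strings(cls, cores) -> "StringCollection":
        return cls(tuple(Sequence.document(c, doc_id=d) for d, c in enumerate(cores, 1)))

    @property
    def m(self) -> int:
        return len(self.docs)

    @property
    def N(self) -> int:
        return sum(len(doc) for doc in self.docs)

    @property
    def sigma(self) -> int:
        """Number of distinct symbols over the collection (including ``$``)."""
        syms = set()
        for doc in self.docs:
            syms.update(doc.text)
        return len(syms)

    def doc(self, d: int) -> Sequence:
        if not 1 <= d <= self.m:
            raise IndexError(f"document {d} out of range 1..{self.m}")
        return self.docs[d - 1]

    def symbols(self) -> set:
        """Distinct non-sentinel symbols occurring in the collection."""
        syms = set()
        for doc in self.docs:
            syms.update(doc.core)
        return syms

    def longest_run(self, c: str) -> int:
        """Length of the longest run of symbol ``c`` over all documents."""
        best = 0
        for doc in self.docs:
            run = 0
            for ch in doc.core:
                run = run + 1 if ch == c else 0
                if run > best:
                    best = run
        return best
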