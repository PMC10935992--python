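"""Compressed stores over heads / insert-heads with predecessor access.

The predecessor structure is the two-layer sampled + differential layout: every
``sample_rate``-th stored position is kept in a sampled array (binary search),
the full position set is kept as gaps between consecutive positions (linear
scan from the sample).  Query cost O(log(chi/b_p) + b_p).

Reconstruction at an arbitrary position i uses the nearest stored record j on
the left: MS[i] = (p_j + k, l_j - k) and ems(i) = (q_j + k, l_j - k, x_j, c_j)
with k = i - j, plus one ISA lookup for the insert point ip(i) = ISA_R[q_j + k].
A reconstructed length of 0 can only happen at the document sentinel, where
MS[i] = (-1, 0) by definition.
"""

from __future__ import annotations

import struct
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .matching_statistics import (EmsEntry, InsertHeadRecord, MsEntry,
                                  compute_ecms, compute_heads)
from .reference_index import ReferenceIndex
from .sequence import Sequence, StringCollection, symbol_rank

_GAP_MAX = 2**32 - 1


class PredecessorIndex:
    """Two-layer predecessor structure over a strictly increasing position set."""

    def __init__(self, positions, sample_rate: int = 32):
        if sample_rate < 1:
            raise ValueError("sample_rate must be >= 1")
        pos = [int(x) for x in positions]
        if not pos or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be non-empty and strictly increasing")
        gaps = [pos[0]] + [b - a for a, b in zip(pos, pos[1:])]
        assert max(gaps) <= _GAP_MAX, "gap overflows 32-bit differential encoding"
        self.sample_rate = sample_rate
        self.samples = pos[::sample_rate]
        self.gaps = np.asarray(gaps, dtype=np.uint32)
        self._size = len(pos)

    def __len__(self) -> int:
        return self._size

    def predecessor_index(self, x: int) -> int:
        """Rank (0-based) of the largest stored position <= x."""
        k = bisect_right(self.samples, x) - 1
        if k < 0:
            raise ValueError(f"{x} is below the first stored position")
        idx = k * self.sample_rate
        pos = self.samples[k]
        while idx + 1 < self._size and pos + int(self.gaps[idx + 1]) <= x:
            idx += 1
            pos += int(self.gaps[idx])
        return idx

    def predecessor(self, x: int) -> int:
        """The largest stored position <= x."""
        return self._decode(self.predecessor_index(x))

    def successor(self, x: int) -> int:
        """The smallest stored position > x (error when none exists)."""
        idx = self.predecessor_index(x) + 1
        if idx >= self._size:
            raise ValueError(f"no stored position above {x}")
        return self._decode(idx)

    def _decode(self, idx: int) -> int:
        k = idx // self.sample_rate
        pos = self.samples[k]
        for t in range(k * self.sample_rate + 1, idx + 1):
            pos += int(self.gaps[t])
        return pos

    def positions(self) -> List[int]:
        """Decode the full stored set (round-trip check surface)."""
        out = []
        pos = 0
        for g in self.gaps:
            pos += int(g)
            out.append(pos)
        return out


@dataclass
class _DocHeads:
    length: int                 # |S_d|
    pos: np.ndarray             # head positions, increasing, pos[0] = 1
    pred: PredecessorIndex


class CmsStore:
    """Per-document head records (j, p_j, l_j) with predecessor access.

    Documents are kept behind one facade keyed by (d, i); the reconstruction
    arithmetic is per document.
    """

    def __init__(self, sample_rate: int = 32):
        self.sample_rate = sample_rate
        self._docs: Dict[int, Tuple[_DocHeads, np.ndarray, np.ndarray]] = {}

    @classmethod
    def build(cls, C: StringCollection, idx: ReferenceIndex,
              sample_rate: int = 32, fast_path: bool = True) -> "CmsStore":
        store = cls(sample_rate)
        for doc in C.docs:
            heads = compute_heads(doc, idx, fast_path=fast_path)
            store.add_document(doc.doc_id, len(doc), heads)
        return store

    def add_document(self, d: int, length: int,
                     heads: List[Tuple[int, MsEntry]]) -> None:
        pos = np.asarray([j for j, _ in heads], dtype=np.int64)
        if pos.size == 0 or pos[0] != 1:
            raise ValueError("position 1 must be a head")
        p = np.asarray([ms.p for _, ms in heads], dtype=np.int64)
        ell = np.asarray([ms.ell for _, ms in heads], dtype=np.int64)
        dh = _DocHeads(length=length, pos=pos,
                       pred=PredecessorIndex(pos.tolist(), self.sample_rate))
        self._docs[d] = (dh, p, ell)

    def chi(self, d: int = 1) -> int:
        return len(self._docs[d][0].pos)

    def ms_at(self, i: int, d: int = 1) -> MsEntry:
        """Exact MS[i] reconstructed from the nearest head on the left."""
        dh, p, ell = self._docs[d]
        if not 1 <= i <= dh.length:
            raise IndexError(f"position {i} out of range 1..{dh.length}")
        jidx = dh.pred.predecessor_index(i)
        k = i - int(dh.pos[jidx])
        length = int(ell[jidx]) - k
        assert length >= 0, "gap between heads exceeds stored run"
        if length == 0:
            return MsEntry(-1, 0)
        return MsEntry(int(p[jidx]) + k, length)


@dataclass
class _DocEcms:
    length: int
    pos: np.ndarray             # insert-head positions
    q: np.ndarray
    ell: np.ndarray
    x_is_s: np.ndarray          # bool
    c_rank: np.ndarray
    c_char: List[str]
    is_head: np.ndarray         # bool: also a plain head
    ip: np.ndarray
    pred: PredecessorIndex


class EcmsStore:
    """Per-document insert-head records with predecessor access and random
    access to ems(i)/ip(i) for any position of any document."""

    def __init__(self, ref: ReferenceIndex, sample_rate: int = 32):
        self.ref = ref
        self.sample_rate = sample_rate
        self._docs: Dict[int, _DocEcms] = {}

    @classmethod
    def build(cls, C: StringCollection, idx: ReferenceIndex,
              sample_rate: int = 32, fast_path: bool = True) -> "EcmsStore":
        store = cls(idx, sample_rate)
        for doc in C.docs:
            store.add_document(doc.doc_id, len(doc),
                               compute_ecms(doc, idx, fast_path=fast_path))
        return store

    def add_document(self, d: int, length: int,
                     records: List[InsertHeadRecord]) -> None:
        if not records or records[0].j != 1:
            raise ValueError("position 1 must be an insert-head")
        pos = np.asarray([r.j for r in records], dtype=np.int64)
        self._docs[d] = _DocEcms(
            length=length,
            pos=pos,
            q=np.asarray([r.ems.q for r in records], dtype=np.int64),
            ell=np.asarray([r.ems.ell for r in records], dtype=np.int64),
            x_is_s=np.asarray([r.ems.x == "S" for r in records], dtype=bool),
            c_rank=np.asarray([symbol_rank(r.ems.c) for r in records],
                              dtype=np.int64),
            c_char=[r.ems.c for r in records],
            is_head=np.asarray([r.is_head for r in records], dtype=bool),
            ip=np.asarray([r.ip for r in records], dtype=np.int64),
            pred=PredecessorIndex(pos.tolist(), self.sample_rate),
        )

    @property
    def doc_ids(self) -> List[int]:
        return sorted(self._docs)

    def doc_length(self, d: int) -> int:
        return self._docs[d].length

    def chi_prime(self, d: int) -> int:
        return len(self._docs[d].pos)

    def head_count(self, d: int) -> int:
        return int(self._docs[d].is_head.sum())

    def records(self, d: int) -> List[InsertHeadRecord]:
        dc = self._docs[d]
        return [InsertHeadRecord(d=d, j=int(dc.pos[t]),
                                 ems=EmsEntry(int(dc.q[t]), int(dc.ell[t]),
                                              "S" if dc.x_is_s[t] else "L",
                                              dc.c_char[t]),
                                 ip=int(dc.ip[t]), is_head=bool(dc.is_head[t]))
                for t in range(len(dc.pos))]

    def i_head(self, d: int, i: int) -> int:
        """The insert-head position pred_{H'}(i) within document d."""
        dc = self._docs[d]
        i = min(i, dc.length)
        return dc.pred.predecessor(i)

    def next_i_head(self, d: int, i: int) -> int:
        """The first insert-head strictly after position i in document d."""
        return self._docs[d].pred.successor(i)

    def ems_at(self, d: int, i: int) -> Tuple[EmsEntry, int]:
        """ems(i) and ip(i) reconstructed from the nearest insert-head plus
        one ISA lookup."""
        dc = self._docs[d]
        if not 1 <= i <= dc.length:
            raise IndexError(f"position {i} out of range 1..{dc.length}")
        t = dc.pred.predecessor_index(i)
        k = i - int(dc.pos[t])
        ell = int(dc.ell[t]) - k
        assert ell >= 0, "gap between insert-heads exceeds stored run"
        q = int(dc.q[t]) + k
        ip = int(self.ref.isa[q])
        return EmsEntry(q, ell, "S" if dc.x_is_s[t] else "L", dc.c_char[t]), ip

    # -- binary persistence (versioned little-endian layout) -----------------

    _MAGIC = b"ECMS\x00\x01"

    def dump(self, path) -> None:
        """Versioned little-endian dump: magic, m, then per document
        (d, |S_d|, chi'), then per insert-head (j, q, ell, x, c)."""
        with open(path, "wb") as fh:
            fh.write(self._MAGIC)
            fh.write(struct.pack("<I", len(self._docs)))
            for d in self.doc_ids:
                dc = self._docs[d]
                fh.write(struct.pack("<III", d, dc.length, len(dc.pos)))
                for t in range(len(dc.pos)):
                    fh.write(struct.pack(
                        "<IIIBBB", int(dc.pos[t]), int(dc.q[t]),
                        int(dc.ell[t]), 1 if dc.x_is_s[t] else 0,
                        ord(dc.c_char[t]), 1 if dc.is_head[t] else 0))

    @classmethod
    def load(cls, path, ref: ReferenceIndex,
             sample_rate: int = 32) -> "EcmsStore":
        store = cls(ref, sample_rate)
        with open(path, "rb") as fh:
            if fh.read(len(cls._MAGIC)) != cls._MAGIC:
                raise ValueError("not an eCMS dump (bad magic/version)")
            (m,) = struct.unpack("<I", fh.read(4))
            for _ in range(m):
                d, length, chi = struct.unpack("<III", fh.read(12))
                recs = []
                for _ in range(chi):
                    j, q, ell, xs, cc, ih = struct.unpack("<IIIBBB", fh.read(15))
                    ems = EmsEntry(q, ell, "S" if xs else "L", chr(cc))
                    recs.append(InsertHeadRecord(d=d, j=j, ems=ems,
                                                 ip=int(ref.isa[q]),
                                                 is_head=bool(ih)))
                store.add_document(d, length, recs)
        return store
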