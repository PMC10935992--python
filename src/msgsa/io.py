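"""FASTA input, GSA output, run reports.

Sequences are validated against a configurable alphabet (default: IUPAC
nucleotide codes — ambiguity codes such as N are ordinary symbols here, not
replaced).  Output coordinates are 1-based.
"""

from __future__ import annotations

import gzip
import json
import struct
from typing import Iterable, Optional, Set, Tuple

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .gsa import GsaArray
from .sequence import Sequence, StringCollection

#: IUPAC nucleotide codes (plus U); used as the default validation alphabet
IUPAC_NUCLEOTIDES: Set[str] = set("ACGTURYSWKMBDHVN")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_records(path) -> Iterable[Tuple[str, str]]:
    with _open_text(path) as fh:
        yield from SimpleFastaParser(fh)


def read_fasta(path, alphabet: Optional[Set[str]] = None) -> StringCollection:
    """Read a multi-FASTA file into a collection: records in file order become
    S_1..S_m, symbols upper-cased, '$' appended per record."""
    alphabet = IUPAC_NUCLEOTIDES if alphabet is None else alphabet
    docs = []
    for d, (header, seq) in enumerate(_read_records(path), start=1):
        seq = seq.upper()
        if not seq:
            raise ValueError(f"empty record {header!r} (record {d})")
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(
                f"illegal symbol(s) {sorted(bad)} in record {header!r} "
                f"(record {d}); allowed: {''.join(sorted(alphabet))}")
        docs.append(Sequence.document(seq, doc_id=d))
    if not docs:
        raise ValueError(f"no FASTA records in {path}")
    return StringCollection(tuple(docs))


def read_reference(path, alphabet: Optional[Set[str]] = None) -> Sequence:
    """Read a single-FASTA reference (first record; '#' appended)."""
    alphabet = IUPAC_NUCLEOTIDES if alphabet is None else alphabet
    for header, seq in _read_records(path):
        seq = seq.upper()
        if not seq:
            raise ValueError(f"empty reference record {header!r}")
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"illegal symbol(s) {sorted(bad)} in reference")
        return Sequence.reference(seq)
    raise ValueError(f"no FASTA records in {path}")


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    """Write (name, core-sequence) records as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


_GSA_MAGIC = b"MSGSA\x00\x00\x01"  # 8-byte magic + version


def write_gsa(gsa: GsaArray, path, mode: str = "text") -> None:
    """Write the GSA: text mode is TSV lines ``rank<TAB>d<TAB>j`` (1-based);
    binary mode is the 8-byte magic/version header followed by little-endian
    32-bit (d, j) pairs.  Round-trips losslessly via :func:`read_gsa`."""
    if len(gsa) == 0:
        raise ValueError("refusing to write an empty GSA")
    if mode == "text":
        with open(path, "w") as fh:
            for r, (d, j) in enumerate(gsa.entries, start=1):
                fh.write(f"{r}\t{d}\t{j}\n")
    elif mode == "binary":
        with open(path, "wb") as fh:
            fh.write(_GSA_MAGIC)
            fh.write(struct.pack("<I", len(gsa)))
            for d, j in gsa.entries:
                fh.write(struct.pack("<II", d, j))
    else:
        raise ValueError(f"unknown mode {mode!r}")


def read_gsa(path, mode: str = "text") -> GsaArray:
    if mode == "text":
        pairs = []
        with open(path) as fh:
            for line in fh:
                _r, d, j = line.split("\t")
                pairs.append((int(d), int(j)))
        return GsaArray.from_pairs(pairs)
    if mode == "binary":
        with open(path, "rb") as fh:
            if fh.read(len(_GSA_MAGIC)) != _GSA_MAGIC:
                raise ValueError("not a GSA dump (bad magic/version)")
            (n,) = struct.unpack("<I", fh.read(4))
            pairs = [struct.unpack("<II", fh.read(8)) for _ in range(n)]
        return GsaArray.from_pairs(pairs)
    raise ValueError(f"unknown mode {mode!r}")


def write_report(report: dict, path) -> None:
    """JSON run report with the phase tallies (heads, insert-heads, S* count,
    bucket count, ...)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
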