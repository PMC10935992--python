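"""Synthetic collections: mutated copies of a random reference.

Emulates collections of highly similar genomes: a uniform random A/C/G/T
reference and m copies, each with substitutions at floor(rate * ref_len)
distinct uniformly chosen positions, the substitute drawn uniformly from the
three other nucleotides (never the original).  Deterministic under a seed.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .sequence import Sequence, StringCollection

_NUCS = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_collection(ref_len: int, m: int, rate: float,
                        seed: int) -> Tuple[Sequence, StringCollection]:
    """Return (reference ending in '#', collection of m mutated '$'-terminated
    copies).  ``rate`` is the per-copy substituted fraction, in [0, 1]."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if ref_len < 1 or m < 1:
        raise ValueError("ref_len and m must be >= 1")
    rng = np.random.default_rng(seed)
    ref = rng.integers(0, 4, size=ref_len)
    k = int(rate * ref_len)
    docs = []
    for d in range(1, m + 1):
        copy = ref.copy()
        if k:
            sites = rng.choice(ref_len, size=k, replace=False)
            # uniform over the 3 other nucleotides, excluding the original
            shift = rng.integers(1, 4, size=k)
            copy[sites] = (copy[sites] + shift) % 4
        core = _NUCS[copy].tobytes().decode("ascii")
        docs.append(Sequence.document(core, doc_id=d))
    ref_seq = Sequence.reference(_NUCS[ref].tobytes().decode("ascii"))
    return ref_seq, StringCollection(tuple(docs))
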