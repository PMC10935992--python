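"""Shared fixtures: the worked example and randomized instance factories."""

import random

import pytest

import msgsa as M

#: the worked example: a 16 bp reference and one similar 16 bp document
WORKED_R = "TGATGGCACAGATACT"
WORKED_S = "GATGGCACATTGATGG"


@pytest.fixture(scope="session")
def worked():
    """Reference index, document and collection of the worked example."""
    R = M.Sequence.reference(WORKED_R)
    S = M.Sequence.document(WORKED_S, doc_id=1)
    C = M.StringCollection((S,))
    idx = M.ReferenceIndex(M.augment_reference(R, C))
    return {"R": R, "S": S, "C": C, "idx": idx}


def random_collection(rng: random.Random, max_m: int = 4, max_len: int = 14,
                      alphabets=("AB", "ABC", "ACGT")):
    """A collection of independent random strings (stresses repeats/ties)."""
    m = rng.randint(1, max_m)
    alpha = rng.choice(alphabets)
    cores = ["".join(rng.choice(alpha) for _ in range(rng.randint(1, max_len)))
             for _ in range(m)]
    return M.StringCollection.from_strings(cores)


def indexed(C, ref_core=None):
    """Reference index for C (default reference: S_1)."""
    R = M.Sequence.reference(ref_core if ref_core is not None else C.doc(1).core)
    return M.ReferenceIndex(M.augment_reference(R, C))
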