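"""Nucleotide sequence helpers (2-bit encoding, reverse complement, random sequence)."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> 2-bit code; anything that is not ACGT (upper or lower) maps to 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes 0..3 (A,C,G,T); non-ACGT -> 4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact 2-bit packed k-mer values (k <= 32) and a validity mask.

    A window is invalid if it contains any non-ACGT character.
    """
    if k > 32:
        raise ValueError("k must be <= 32 for exact packing")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | (codes[j : j + n] & np.uint8(3)).astype(np.uint64)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return h, valid
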