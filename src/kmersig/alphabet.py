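"""DNA alphabet helpers shared across the package.

All k-mer vectors in this package are indexed lexicographically with
A < C < G < T, i.e. a k-mer maps to its base-4 integer code with A=0,
C=1, G=2, T=3 and the first base most significant.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> base code lookup; N (and anything else) maps to -1
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_TABLE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A,C,G,T -> 0..3, N -> -1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def kmer_strings(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic (= code) order."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in BASES]
    return kmers


def kmer_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + BASE_INDEX[b]
    return code


def revcomp_codes(k: int) -> np.ndarray:
    """Vector mapping each k-mer code to the code of its reverse complement."""
    codes = np.arange(4**k)
    rc = np.zeros_like(codes)
    for j in range(k):
        digit = (codes >> (2 * j)) & 3  # base at position k-1-j
        rc = rc * 4 + (3 - digit)
    return rc
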