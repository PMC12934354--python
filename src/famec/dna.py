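"""Small DNA byte-level helpers shared across the codec."""

from __future__ import annotations

import numpy as np

A, C, G, T = 65, 67, 71, 84  # ASCII 'A' 'C' 'G' 'T'
ACGT = b"ACGT"

# complement lookup over all byte values; non-ACGT bytes map to themselves
_COMP = np.arange(256, dtype=np.uint8)
for x, y in ((A, T), (C, G), (G, C), (T, A)):
    _COMP[x] = y

_IS_ACGT = np.zeros(256, dtype=bool)
_IS_ACGT[[A, C, G, T]] = True

# 2-bit packing for k-mer codes; non-ACGT bytes get the sentinel 255
BASE2BITS = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(ACGT):
    BASE2BITS[b] = i


def complement(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


def revcomp_bytes(seq: bytes) -> bytes:
    """Reverse complement; non-ACGT bytes are kept (complemented to self)."""
    arr = np.frombuffer(seq, dtype=np.uint8)
    return _COMP[arr][::-1].tobytes()


def acgt_mask(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of positions holding an uppercase A/C/G/T byte."""
    return _IS_ACGT[arr]


def map_to_acgt(seq: bytes) -> bytes:
    """Replace every non-ACGT byte by 'A'.

    Used when a contig joins the reference buffer, which is kept over the
    strict {A,C,G,T} alphabet; matching always compares against the stored
    reference bytes, so the substitution never breaks losslessness.
    """
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    arr[~_IS_ACGT[arr]] = A
    return arr.tobytes()


def is_acgt_byte(b: int) -> bool:
    return bool(_IS_ACGT[b])
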