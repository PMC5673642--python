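"""Numeric 2-bit-plus-N encoding of DNA shared by the simulator and aligner.

Bases map A,C,G,T -> 0,1,2,3 and N -> 4.  Codes live in uint8 arrays so
whole read sets can be held and sliced as matrices.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(BASES):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i

_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array; raises on invalid letters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    if (codes == 255).any():
        pos = int(np.argmax(codes == 255))
        raise ValueError(f"invalid residue {seq[pos]!r} at position {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers (positions containing N get code -1).

    Returns an int64 array of length len(codes)-k+1.  Requires 4**k to fit
    in int64, i.e. k <= 31.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = out * 4 + vals[i : i + n]
    # any window containing an N is invalid
    bad = vals >= 4
    if bad.any():
        win_bad = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
        out[win_bad] = -1
    return out
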