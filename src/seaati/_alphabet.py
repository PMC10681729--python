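"""Low-level DNA alphabet helpers.

Everything downstream encodes bases as integers A=0, C=1, G=2, T=3 (this
ordering makes numeric k-mer-code order coincide with lexicographic order
of the k-mer strings). Any other character encodes to -1 and marks the
window containing it as invalid.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

BASES = "ACGT"
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.int8)

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_COMP_TRANS = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant, case preserved)."""
    return seq.translate(_COMP_TRANS)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode one sequence to an int8 vector; non-ACGT become -1."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: Sequence[int]) -> str:
    return "".join(BASES[c] for c in codes)


def encode_matrix(seqs: Iterable[str]) -> np.ndarray:
    """Encode uniform-length sequences into an (n, L) int8 matrix.

    Raises ValueError if lengths differ.
    """
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have uniform length")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[buf].reshape(len(seqs), L)


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of an encoded matrix (-1 maps to -1)."""
    out = np.where(mat >= 0, 3 - mat, -1).astype(np.int8)
    return out[:, ::-1]


def kmer_to_code(kmer: str) -> int:
    codes = encode(kmer)
    if (codes < 0).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    code = 0
    for c in codes:
        code = code * 4 + int(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def window_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all length-k windows of every row.

    Returns an (n, L-k+1) int64 array; windows containing an invalid
    base get code -1.
    """
    n, L = mat.shape
    if k > L:
        raise ValueError(f"k={k} exceeds read length {L}")
    win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win.astype(np.int64) @ pow4
    invalid = (win < 0).any(axis=2)
    codes[invalid] = -1
    return codes


def revcomp_code_table(k: int) -> np.ndarray:
    """Lookup table mapping every k-mer code to its reverse-complement code."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc
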