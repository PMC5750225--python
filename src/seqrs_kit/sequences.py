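"""Shared RNA sequence utilities: alphabet, integer encoding, k-mer codes.

The alphabet is RNA (A, C, G, U); any T on input is mapped to U. Bases are
encoded A=0, C=1, G=2, U=3, so the numeric order of encoded k-mers coincides
with lexicographic order over the RNA alphabet — rank tie-breaking relies on
this.
"""

from __future__ import annotations

import numpy as np

RNA_BASES = "ACGU"

#: byte-value -> 2-bit code lookup (255 marks an invalid character)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(RNA_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("T")] = 3
_CODE[ord("t")] = 3


def normalize_rna(seq: str) -> str:
    """Uppercase and map T->U; raise on characters outside the alphabet."""
    s = seq.upper().replace("T", "U")
    if any(c not in RNA_BASES for c in s):
        bad = sorted({c for c in s if c not in RNA_BASES})
        raise ValueError(f"non-RNA characters in sequence: {bad}")
    return s


def encode_seqs(seqs, length: int | None = None) -> np.ndarray:
    """Encode equal-length sequences to an (n, L) uint8 matrix of base codes."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = length if length is not None else len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("encode_seqs requires equal-length sequences")
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE[buf].reshape(len(seqs), L)
    if (codes == 255).any():
        raise ValueError("non-RNA characters in sequence set")
    return codes


def encode_seq(seq: str) -> np.ndarray:
    return encode_seqs([seq])[0]


_ASCII = np.frombuffer(RNA_BASES.encode("ascii"), dtype=np.uint8)


def decode_codes(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def decode_matrix(mat: np.ndarray) -> list:
    """Decode an (n, L) code matrix to a list of n strings."""
    n, L = mat.shape
    blob = _ASCII[mat].tobytes().decode("ascii")
    return [blob[i * L : (i + 1) * L] for i in range(n)]


def kmer_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every length-k window of every row of `mat`.

    Returns an (n, L-k+1) int64 array; rows shorter than k yield zero columns.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n, L = mat.shape
    if L < k:
        return np.empty((n, 0), dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(mat, k, axis=1)
    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return win.astype(np.int64) @ pows


def kmer_to_code(kmer: str) -> int:
    code = 0
    for c in normalize_rna(kmer):
        code = code * 4 + RNA_BASES.index(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(RNA_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def base_count_per_code(k: int, base: str = "A") -> np.ndarray:
    """For every k-mer code in [0, 4^k): how many positions equal `base`."""
    b = RNA_BASES.index(base)
    idx = np.arange(4**k, dtype=np.int64)
    n = np.zeros(4**k, dtype=np.int64)
    for j in range(k):
        n += ((idx >> (2 * j)) & 3) == b
    return n
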