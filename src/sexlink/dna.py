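"""Nucleotide encoding primitives shared across the package.

K-mers are held as 2-bit-packed integer codes (A=0, C=1, G=2, T=3) in
``uint64`` arrays, which caps k at 31. The canonical form of a word is the
lexicographic minimum of the word and its reverse complement; because the
2-bit encoding is alphabetical, lexicographic order on words equals numeric
order on codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
MAX_K = 31

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; non-ACGT bases become 255."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    valid = codes < 4
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    out[valid] = lut[codes[valid]]
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(word: str) -> str:
    rc = revcomp(word)
    return word if word <= rc else rc


def _combine(a: np.ndarray, la: int, b: np.ndarray, lb: int) -> np.ndarray:
    # concatenate length-la codes with length-lb codes starting la later
    n = min(a.size, b.size - la)
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    return (a[:n] << np.uint64(2 * lb)) | b[la : la + n]


def kmer_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-window codes of a uint8 base array, plus a validity mask.

    Windows containing any non-ACGT base are marked invalid (their code is
    meaningless and must be filtered with the mask). Uses O(log k)
    vectorised doubling passes rather than a per-base loop.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = base_codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (base_codes > 3).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0

    piece = np.where(base_codes > 3, 0, base_codes).astype(np.uint64)
    plen = 1
    acc: np.ndarray | None = None
    acc_len = 0
    rem = k
    while rem:
        if rem & 1:
            if acc is None:
                acc, acc_len = piece, plen
            else:
                acc = _combine(acc, acc_len, piece, plen)
                acc_len += plen
        rem >>= 1
        if rem:
            piece = _combine(piece, plen, piece, plen)
            plen *= 2
    assert acc is not None and acc_len == k
    return acc[:n], valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of each packed k-mer code."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        rc = (rc << two) | ((tmp & three) ^ three)
        tmp >>= two
    return rc


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.minimum(codes, revcomp_codes(codes, k))


def code_to_kmer(code: int, k: int) -> str:
    out = []
    c = int(code)
    for _ in range(k):
        out.append(BASES[c & 3])
        c >>= 2
    return "".join(reversed(out))


def kmer_to_code(word: str) -> int:
    c = 0
    for ch in word:
        v = _ENC[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT base {ch!r} in k-mer {word!r}")
        c = (c << 2) | int(v)
    return c


def sequence_kmer_codes(seq: str, k: int, canonicalize: bool = True) -> np.ndarray:
    """Valid (canonical) k-mer codes of a sequence, in positional order."""
    codes, valid = kmer_codes(encode(seq), k)
    codes = codes[valid]
    if canonicalize:
        codes = canonical_codes(codes, k)
    return codes
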