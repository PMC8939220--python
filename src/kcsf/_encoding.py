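"""2-bit packed k-mer encoding.

A k-mer over {A,C,G,T} with k <= 31 packs into a single uint64 with A=0,
C=1, G=2, T=3, most significant base first.  Because the base order
matches the lexicographic order of the letters, comparing packed integers
is the same as comparing the strings, which makes canonicalization (min
of a k-mer and its reverse complement) a numeric ``min``.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"

# byte -> code lookup for fast sequence translation; 255 marks invalid,
# 4 marks N (valid letter, but windows containing it are skipped)
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c
_LUT[ord("N")] = 4
_LUT[ord("n")] = 4


def encode_kmer(kmer: str) -> int:
    """Pack a k-mer string into its 2-bit integer representation."""
    if not 1 <= len(kmer) <= MAX_K:
        raise ValueError(f"k-mer length must be in [1, {MAX_K}], got {len(kmer)}")
    x = 0
    for ch in kmer.upper():
        try:
            x = (x << 2) | _BASE_TO_CODE[ch]
        except KeyError:
            raise ValueError(f"invalid base {ch!r} in k-mer {kmer!r}") from None
    return x


def decode_kmer(packed: int, k: int) -> str:
    """Unpack a 2-bit integer back into its k-mer string."""
    return "".join(_CODE_TO_BASE[(int(packed) >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_packed(packed: int, k: int) -> int:
    """Reverse complement of a packed k-mer."""
    x = int(packed)
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (x & 3))
        x >>= 2
    return rc


def canonical_packed(packed: int, k: int) -> int:
    return min(int(packed), revcomp_packed(packed, k))


def sequence_to_codes(seq: str) -> np.ndarray:
    """Translate a sequence to base codes (0-3), 4 for N, 255 for invalid.

    Raises on characters outside {A,C,G,T,N} (case-insensitive).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"invalid character {bad!r} in sequence")
    return codes


def packed_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-windows of a code array as packed uint64, plus a validity mask.

    A window is valid when it contains no N.  Returns (packed, valid) with
    one entry per window position; empty arrays when the sequence is
    shorter than k.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    nw = n - k + 1
    is_n = codes == 4
    safe = np.where(is_n, 0, codes).astype(np.uint64)
    fwd = np.zeros(nw, dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | safe[i : i + nw]
    # valid iff no N among the k bases of the window
    bad = np.convolve(is_n.astype(np.int32), np.ones(k, dtype=np.int32), mode="valid") > 0
    return fwd, ~bad


def revcomp_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse complements of all k-windows (same positions as packed_windows)."""
    n = codes.shape[0]
    nw = n - k + 1
    comp = np.where(codes == 4, 0, 3 - codes).astype(np.uint64)
    rc = np.zeros(nw, dtype=np.uint64)
    for i in range(k):
        rc = (rc << np.uint64(2)) | comp[k - 1 - i : k - 1 - i + nw]
    return rc
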