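"""Canonical, length-limited prefix-free codes over count values.

The CSF stores, per key, the codeword of its value; retrieval XORs three
fixed-width bit windows and decodes the prefix at the front.  The code
must therefore be instantaneous, have bounded codeword length (the
window width), and be reconstructible from compact metadata.  Canonical
Huffman codes fit all three: optimal lengths are computed by Huffman's
algorithm, falling back to the package-merge algorithm when the
unconstrained depth exceeds the cap (package-merge yields optimal
length-limited lengths), and codewords are then assigned canonically in
(length, symbol) order so only symbols and lengths need storing.

Average codeword length lies within [H0, H0 + 1) bits of the build
histogram — the usual Huffman bound — with the degenerate single-symbol
alphabet coded in 0 bits.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PrefixCode", "build_code", "to_signed", "from_signed"]


def _huffman_lengths(freqs: list[int]) -> list[int]:
    """Unconstrained optimal codeword lengths (depth of each Huffman leaf)."""
    n = len(freqs)
    if n == 1:
        return [0]
    # nodes carry their leaves as ((leaf index, depth), ...)
    heap = [(f, i, ((i, 0),)) for i, f in enumerate(freqs)]
    heapq.heapify(heap)
    tiebreak = n
    while len(heap) > 1:
        f1, _, l1 = heapq.heappop(heap)
        f2, _, l2 = heapq.heappop(heap)
        merged = tuple((leaf, d + 1) for leaf, d in l1 + l2)
        heapq.heappush(heap, (f1 + f2, tiebreak, merged))
        tiebreak += 1
    lengths = [0] * n
    for leaf, d in heap[0][2]:
        lengths[leaf] = d
    return lengths


def _package_merge_lengths(freqs: list[int], max_len: int) -> list[int]:
    """Optimal lengths under a hard length cap (package-merge)."""
    n = len(freqs)
    if n == 1:
        return [0]
    if (1 << max_len) < n:
        raise ValueError(f"max_len={max_len} cannot code {n} symbols")
    order = sorted(range(n), key=lambda i: (freqs[i], i))
    # item = (weight, leaf-count vector over symbols)
    leaves = [(freqs[i], np.eye(1, n, i, dtype=np.int64)[0]) for i in order]
    prev: list[tuple[int, np.ndarray]] = []
    for _ in range(max_len):
        packages = [
            (prev[j][0] + prev[j + 1][0], prev[j][1] + prev[j + 1][1])
            for j in range(0, len(prev) - 1, 2)
        ]
        prev = sorted(leaves + packages, key=lambda t: t[0])
    counts = np.zeros(n, dtype=np.int64)
    for w, vec in prev[: 2 * n - 2]:
        counts += vec
    return [int(c) for c in counts]


@dataclass
class PrefixCode:
    """Canonical prefix-free code; only ``symbols`` and ``lengths`` are stored."""

    symbols: list[int]
    lengths: list[int]
    max_len: int = 32
    # derived at construction
    codewords: dict[int, tuple[int, int]] = field(default=None, repr=False)
    _decode_first: np.ndarray = field(default=None, repr=False)
    _decode_offset: np.ndarray = field(default=None, repr=False)
    _decode_count: np.ndarray = field(default=None, repr=False)
    _canonical_symbols: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.lengths):
            raise ValueError("symbols and lengths must align")
        if any(l > self.max_len for l in self.lengths):
            raise ValueError("codeword length exceeds max_len")
        if len(self.lengths) > 1:
            if any(l < 1 for l in self.lengths):
                raise ValueError("only a single-symbol code may use 0-bit codewords")
            kraft = sum(2.0 ** -l for l in self.lengths)
            if kraft > 1.0 + 1e-12:
                raise ValueError(f"Kraft inequality violated (sum={kraft})")
        self._build_tables()

    def _build_tables(self) -> None:
        order = sorted(range(len(self.symbols)), key=lambda i: (self.lengths[i], self.symbols[i]))
        self.codewords = {}
        maxl = self.max_len
        first = np.zeros(maxl + 1, dtype=np.int64)
        count = np.zeros(maxl + 1, dtype=np.int64)
        offset = np.zeros(maxl + 1, dtype=np.int64)
        self._canonical_symbols = np.array(
            [self.symbols[i] for i in order], dtype=np.int64
        )
        code = 0
        prev_len = None
        for rank, i in enumerate(order):
            l = self.lengths[i]
            if prev_len is None:
                code = 0
            else:
                code = (code + 1) << (l - prev_len)
            if count[l] == 0:
                first[l] = code
                offset[l] = rank
            count[l] += 1
            self.codewords[self.symbols[i]] = (code, l)
            prev_len = l
        self._decode_first = first
        self._decode_count = count
        self._decode_offset = offset

    # -- coding ----------------------------------------------------------
    def encode(self, value: int) -> tuple[int, int]:
        """Return (codeword, length in bits), MSB-first."""
        try:
            return self.codewords[value]
        except KeyError:
            raise KeyError(f"value {value} not in code alphabet") from None

    def decode_window(self, window: int) -> tuple[int, int]:
        """Decode the symbol at the front of a max_len-bit window.

        Returns (symbol, bits consumed).  The window is MSB-aligned: bit
        max_len-1 of ``window`` is the first bit of the stream.
        """
        if len(self.symbols) == 1:
            return self.symbols[0], 0
        for l in range(1, self.max_len + 1):
            if self._decode_count[l] == 0:
                continue
            prefix = window >> (self.max_len - l)
            idx = prefix - int(self._decode_first[l])
            if 0 <= idx < int(self._decode_count[l]):
                return int(self._canonical_symbols[int(self._decode_offset[l]) + idx]), l
        raise ValueError("window does not start with a valid codeword")

    def decode_windows(self, windows: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`decode_window` over a uint64 array."""
        windows = np.asarray(windows, dtype=np.uint64)
        out = np.empty(windows.size, dtype=np.int64)
        if len(self.symbols) == 1:
            out[:] = self.symbols[0]
            return out
        done = np.zeros(windows.size, dtype=bool)
        for l in range(1, self.max_len + 1):
            if self._decode_count[l] == 0:
                continue
            prefix = (windows >> np.uint64(self.max_len - l)).astype(np.int64)
            idx = prefix - self._decode_first[l]
            hit = (~done) & (idx >= 0) & (idx < self._decode_count[l])
            if hit.any():
                out[hit] = self._canonical_symbols[self._decode_offset[l] + idx[hit]]
                done |= hit
            if done.all():
                break
        if not done.all():
            raise ValueError("some windows decode to no codeword")
        return out

    def length_of(self, value: int) -> int:
        return self.codewords[value][1]


def build_code(histogram: dict[int, int], max_len: int = 32) -> PrefixCode:
    """Optimal length-limited canonical code for a value histogram."""
    if not histogram:
        raise ValueError("empty histogram")
    if any(f <= 0 for f in histogram.values()):
        raise ValueError("histogram frequencies must be positive")
    n = len(histogram)
    if n > 1 and max_len < math.ceil(math.log2(n)):
        raise ValueError(f"max_len={max_len} too small for {n} symbols")
    symbols = sorted(histogram)
    freqs = [histogram[s] for s in symbols]
    lengths = _huffman_lengths(freqs)
    if max(lengths) > max_len:
        lengths = _package_merge_lengths(freqs, max_len)
    # the stored width is the realized longest codeword: it is the window
    # width decoders align to, and it never exceeds the requested cap
    return PrefixCode(symbols=symbols, lengths=lengths, max_len=max(1, max(lengths)))


def to_signed(v: int) -> int:
    """Zigzag map Z -> N: 0->0, -1->1, 1->2, -2->3, ... (0 stays dominant)."""
    return 2 * v if v >= 0 else -2 * v - 1


def from_signed(u: int) -> int:
    """Inverse of :func:`to_signed`."""
    return u // 2 if u % 2 == 0 else -(u + 1) // 2
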