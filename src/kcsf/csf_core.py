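"""Compressed static function over GF(2): value storage without keys.

Each key is assigned three pseudo-random windows in a per-chunk bit
array (one window per array third, so the three never coincide).  The
build constrains the XOR of the three windows to equal the key's
codeword under a canonical prefix code of the value distribution; a
query XORs the windows and decodes the prefix.  Per codeword bit this
yields one 3-variable linear equation over GF(2); the system is solved
by hypergraph peeling with dense Gaussian elimination on the residual
2-core, which admits bit-array expansion factors gamma well below the
pure-peeling threshold of ~1.23.

Keys are partitioned into chunks by a top-level hash so elimination
always runs on desk-scale systems; an unlucky chunk is rebuilt with a
bumped seed.  For a single-valued input the code is 0 bits wide and the
structure stores no equations at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._gf2 import solve_xor_csr
from ._hash import hash_with_seed_array, mix_seeds
from .prefix_code import PrefixCode, build_code

__all__ = ["CSFStructure", "build_csf", "csf_query", "solve_gf2"]

DEFAULT_GAMMA = 1.10
DEFAULT_CHUNK_TARGET = 2048
MAX_CHUNK_BITS = 1500
SEED_RETRIES = 8


# ---------------------------------------------------------------------------
# GF(2) solver front end (kernel in _gf2)
# ---------------------------------------------------------------------------

def _solve_flat(
    vars_flat: np.ndarray, eq_ptr: np.ndarray, rhs: np.ndarray, n_vars: int
) -> np.ndarray | None:
    """Solve a sparse XOR system in flattened CSR form; None if unsolvable.

    ``vars_flat[eq_ptr[e]:eq_ptr[e+1]]`` are the (distinct) variables of
    equation e; ``rhs[e]`` its right-hand bit.
    """
    ok, x = solve_xor_csr(
        np.ascontiguousarray(vars_flat, dtype=np.int64),
        np.ascontiguousarray(eq_ptr, dtype=np.int64),
        np.ascontiguousarray(rhs, dtype=np.uint8),
        n_vars,
    )
    return x if ok else None


def solve_gf2(
    equations: list[tuple[list[int] | tuple[int, ...], int]], n_vars: int | None = None
) -> np.ndarray | None:
    """Solve XOR equations ``(positions, bit)``; None when unsolvable.

    Repeated positions within one equation cancel in pairs.  The
    returned uint8 array satisfies every equation (verifiable by
    substitution); unconstrained variables are 0.
    """
    clean_vars: list[int] = []
    ptr = [0]
    rhs_list: list[int] = []
    for positions, bit in equations:
        uniq = set()
        for p in positions:
            if p in uniq:
                uniq.remove(p)
            else:
                uniq.add(p)
        if not uniq:
            if bit & 1:
                return None
            continue
        clean_vars.extend(sorted(uniq))
        ptr.append(len(clean_vars))
        rhs_list.append(bit & 1)
    if n_vars is None:
        n_vars = (max(clean_vars) + 1) if clean_vars else 0
    return _solve_flat(
        np.array(clean_vars, dtype=np.int64),
        np.array(ptr, dtype=np.int64),
        np.array(rhs_list, dtype=np.uint8),
        n_vars,
    )


# ---------------------------------------------------------------------------
# The chunked CSF structure
# ---------------------------------------------------------------------------

@dataclass
class _Chunk:
    seed: int
    seg_len: int  # variables per third of the chunk's bit array
    words: np.ndarray  # packed bit array, 3 * seg_len bits
    attempt: int = 0  # retry index the seed was derived from


@dataclass
class CSFStructure:
    code: PrefixCode
    gamma: float
    seed: int
    num_keys: int
    wlen: int  # window width = longest codeword, bits
    chunks: list[_Chunk] = field(default_factory=list)

    # -- querying --------------------------------------------------------
    def query_many(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=np.uint64)
        out = np.empty(keys.size, dtype=np.int64)
        if len(self.code.symbols) == 1:
            out[:] = self.code.symbols[0]
            return out
        cid = _chunk_ids(keys, self.seed, len(self.chunks))
        for c in range(len(self.chunks)):
            idx = np.flatnonzero(cid == c)
            if idx.size == 0:
                continue
            windows = _read_windows(self.chunks[c], keys[idx], self.wlen)
            out[idx] = self.code.decode_windows(windows)
        return out

    def query(self, key: int) -> int:
        return int(self.query_many(np.array([key], dtype=np.uint64))[0])

    @property
    def payload_bits(self) -> int:
        """Bits in the XOR arrays (excludes code table and metadata)."""
        return sum(3 * c.seg_len for c in self.chunks)


def _chunk_ids(keys: np.ndarray, seed: int, n_chunks: int) -> np.ndarray:
    h = hash_with_seed_array(keys, mix_seeds(seed, 0xA551617))
    return (h % np.uint64(n_chunks)).astype(np.int64)


def _positions(chunk: _Chunk, keys: np.ndarray, wlen: int) -> tuple[np.ndarray, ...]:
    span = np.uint64(chunk.seg_len - wlen + 1)
    ps = []
    for s in range(3):
        h = hash_with_seed_array(keys, mix_seeds(chunk.seed, 0x905 + s))
        ps.append((h % span).astype(np.int64) + s * chunk.seg_len)
    return tuple(ps)


def _read_windows(chunk: _Chunk, keys: np.ndarray, wlen: int) -> np.ndarray:
    p0, p1, p2 = _positions(chunk, keys, wlen)
    words = chunk.words
    win = np.zeros(keys.size, dtype=np.uint64)
    for j in range(wlen):
        bit = np.uint64(0)
        for p in (p0, p1, p2):
            pj = p + j
            bit ^= (words[pj >> 6] >> (pj.astype(np.uint64) & np.uint64(63))) & np.uint64(1)
        win = (win << np.uint64(1)) | bit
    return win  # MSB-aligned: first stream bit at position wlen-1


def build_csf(
    pairs,
    gamma: float = DEFAULT_GAMMA,
    chunk_target: int = DEFAULT_CHUNK_TARGET,
    seed: int = 0,
    max_len: int = 32,
) -> CSFStructure:
    """Build a CSF from ``pairs`` (dict key->value, or (keys, values) arrays).

    ``gamma`` expands each chunk's bit array beyond the information
    content (sum of codeword lengths); values below ~1.09 make the GF(2)
    system unsolvable with high probability.
    """
    if gamma < 1.05:
        raise ValueError(f"gamma must be >= 1.05, got {gamma}")
    keys, values = _as_arrays(pairs)
    if keys.size == 0:
        raise ValueError("empty input")
    order = np.argsort(keys)
    keys, values = keys[order], values[order]
    if keys.size > 1 and (keys[1:] == keys[:-1]).any():
        raise ValueError("duplicate keys")

    vals, mult = np.unique(values, return_counts=True)
    code = build_code({int(v): int(m) for v, m in zip(vals, mult)}, max_len=max_len)
    struct = CSFStructure(
        code=code, gamma=gamma, seed=seed, num_keys=int(keys.size),
        wlen=max(code.lengths),
    )
    if len(code.symbols) == 1:
        return struct  # 0-bit codewords: nothing to store

    lengths = np.array([code.length_of(int(v)) for v in code.symbols], dtype=np.int64)
    sym_index = np.searchsorted(np.array(code.symbols, dtype=np.int64), values)
    key_bits = lengths[sym_index]
    codes = np.array([code.encode(int(v))[0] for v in code.symbols], dtype=np.uint64)
    key_codes = codes[sym_index]

    total_bits = int(key_bits.sum())
    n_chunks = max(
        1,
        -(-keys.size // chunk_target),
        -(-total_bits // MAX_CHUNK_BITS),
    )
    cid = _chunk_ids(keys, seed, n_chunks)
    for c in range(n_chunks):
        idx = np.flatnonzero(cid == c)
        struct.chunks.append(
            _build_chunk(
                keys[idx], key_codes[idx], key_bits[idx], gamma, struct.wlen, seed, c
            )
        )
    return struct


def _build_chunk(
    keys: np.ndarray,
    key_codes: np.ndarray,
    key_bits: np.ndarray,
    gamma: float,
    wlen: int,
    global_seed: int,
    chunk_index: int,
) -> _Chunk:
    total = int(key_bits.sum())
    seg_len = max(wlen + 1, -(-int(np.ceil(gamma * total)) // 3) + wlen)
    n_words = (3 * seg_len + 63) // 64

    if keys.size == 0:
        return _Chunk(
            seed=mix_seeds(global_seed, chunk_index, 0), seg_len=seg_len,
            words=np.zeros(n_words, dtype=np.uint64), attempt=0,
        )

    # flatten per-key codeword bits into equations
    eq_key = np.repeat(np.arange(keys.size), key_bits)
    starts = np.concatenate(([0], np.cumsum(key_bits)))
    j = np.arange(total) - starts[eq_key]
    rhs = ((key_codes[eq_key] >> (key_bits[eq_key] - 1 - j).astype(np.uint64)) & np.uint64(1)).astype(np.uint8)

    for attempt in range(SEED_RETRIES):
        chunk = _Chunk(
            seed=mix_seeds(global_seed, chunk_index, attempt), seg_len=seg_len,
            words=np.zeros(n_words, dtype=np.uint64), attempt=attempt,
        )
        p0, p1, p2 = _positions(chunk, keys, wlen)
        vars_flat = np.empty(3 * total, dtype=np.int64)
        vars_flat[0::3] = p0[eq_key] + j
        vars_flat[1::3] = p1[eq_key] + j
        vars_flat[2::3] = p2[eq_key] + j
        eq_ptr = np.arange(0, 3 * total + 1, 3, dtype=np.int64)
        x = _solve_flat(vars_flat, eq_ptr, rhs, 3 * seg_len)
        if x is not None:
            bits = np.flatnonzero(x.astype(bool)).astype(np.int64)
            np.bitwise_or.at(
                chunk.words, bits >> 6, np.uint64(1) << (bits.astype(np.uint64) & np.uint64(63))
            )
            return chunk
    raise RuntimeError(
        f"chunk {chunk_index}: GF(2) system unsolvable after {SEED_RETRIES} seeds; "
        "increase gamma"
    )


def _as_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, dict):
        if not pairs:
            return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
        keys = np.array([int(k) for k in pairs], dtype=np.uint64)
        values = np.array([int(v) for v in pairs.values()], dtype=np.int64)
        return keys, values
    keys, values = pairs
    return np.asarray(keys, dtype=np.uint64), np.asarray(values, dtype=np.int64)


def csf_query(csf: CSFStructure, key: int) -> int:
    return csf.query(key)
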