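"""Bloom filter sized to a target false-positive rate.

A filter over n keys at false-positive rate eps is dimensioned at
``ceil(n * log2(e) * log2(1/eps))`` bits — about ``1.44 * log2(1/eps)``
bits per key, the classical optimum — with ``round(ln 2 * m/n)`` hash
functions.  Probe positions are derived by double hashing (h1 + i*h2
mod m) from two splitmix64 hashes, so querying is O(num_hashes) with two
base hash evaluations.  Inserted keys are always reported present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._hash import hash_with_seed, hash_with_seed_array, mix_seeds

__all__ = ["BloomFilter", "build_bloom", "bloom_query"]

LOG2_E = math.log2(math.e)


@dataclass
class BloomFilter:
    m_bits: int
    num_hashes: int
    target_fp: float
    seed: int
    n_inserted: int = 0
    words: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.words is None:
            self.words = np.zeros((self.m_bits + 63) // 64, dtype=np.uint64)

    # -- probe positions -------------------------------------------------
    def _probes(self, keys: np.ndarray) -> np.ndarray:
        """(num_hashes, n) array of bit positions for each key."""
        h1 = hash_with_seed_array(keys, self.seed)
        h2 = hash_with_seed_array(keys, mix_seeds(self.seed, 0xB100)) | np.uint64(1)
        m = np.uint64(self.m_bits)
        return np.stack(
            [(h1 + np.uint64(i) * h2) % m for i in range(self.num_hashes)]
        )

    def insert_many(self, keys: np.ndarray) -> None:
        keys = np.asarray(keys, dtype=np.uint64)
        if keys.size == 0:
            return
        if self.m_bits == 0:
            raise ValueError("cannot insert into a degenerate (empty) filter")
        pos = self._probes(keys).ravel()
        np.bitwise_or.at(
            self.words, (pos >> np.uint64(6)).astype(np.int64), np.uint64(1) << (pos & np.uint64(63))
        )
        self.n_inserted += int(keys.size)

    def query_many(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=np.uint64)
        if self.m_bits == 0 or keys.size == 0:
            return np.zeros(keys.size, dtype=bool)
        pos = self._probes(keys)
        hit = (
            self.words[(pos >> np.uint64(6)).astype(np.int64)]
            >> (pos & np.uint64(63))
        ) & np.uint64(1)
        return hit.all(axis=0).astype(bool)

    def query(self, key: int) -> bool:
        return bool(self.query_many(np.array([key], dtype=np.uint64))[0])

    @property
    def payload_bits(self) -> int:
        return self.m_bits


def build_bloom(
    keys: np.ndarray | set, epsilon: float, seed: int = 0
) -> BloomFilter:
    """Build a filter over packed keys with expected FP rate ``epsilon``.

    An empty key set yields a degenerate zero-bit filter that answers
    negative for every query.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    if isinstance(keys, (set, frozenset, list, tuple)):
        keys = np.array(sorted(int(x) for x in keys), dtype=np.uint64)
    keys = np.asarray(keys, dtype=np.uint64)
    n = int(keys.size)
    if n == 0:
        return BloomFilter(m_bits=0, num_hashes=1, target_fp=epsilon, seed=seed)
    m_bits = math.ceil(n * LOG2_E * math.log2(1.0 / epsilon))
    m_bits = max(m_bits, 1)
    num_hashes = max(1, round(math.log(2) * m_bits / n))
    bf = BloomFilter(m_bits=m_bits, num_hashes=num_hashes, target_fp=epsilon, seed=seed)
    bf.insert_many(keys)
    return bf


def bloom_query(bf: BloomFilter, key: int) -> bool:
    return bf.query(key)
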