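"""Hash-ordered minimizers of k-mers and minimizer-keyed count buckets.

The minimizer of a k-mer q is its length-m substring that is smallest
under a total order on m-mers.  The order here is ``(splitmix64 hash,
m-mer value)`` under a configurable seed — a hash order has far better
statistical behaviour than the lexicographic one, which concentrates
minimizers on poly-A-like strings.  Minimizers act as a locality-
sensitive footprint: k-mers that overlap in a genome usually share a
minimizer, and — the property this package exploits — usually share a
count, so grouping count values by minimizer yields many single-valued
buckets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encoding import decode_kmer, encode_kmer
from ._hash import hash_with_seed, hash_with_seed_array

__all__ = ["MinimizerScheme", "Bucket", "minimizer", "bucket_counts", "bucket_majority"]

DEFAULT_ORDER_SEED = 0x5EED_1234_ABCD_0042


@dataclass(frozen=True)
class MinimizerScheme:
    """Minimizer length m plus the seed of the hash defining the m-mer order."""

    m: int
    order_seed: int = DEFAULT_ORDER_SEED

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"minimizer length must be >= 1, got {self.m}")


@dataclass
class Bucket:
    """Summary of the count multiset of one minimizer bucket."""

    minimizer: str
    min_count: int
    max_count: int
    size: int
    majority_count: int | None = None

    def ambiguous(self, delta: int = 0) -> bool:
        """A bucket collides when it holds counts differing by more than delta."""
        return self.max_count - self.min_count > delta


def minimizer(q: str, scheme: MinimizerScheme) -> str:
    """The length-m window of q minimal under the scheme's hash order.

    Equal windows tie-break to the leftmost occurrence; distinct windows
    with colliding hashes tie-break to the smaller m-mer, keeping the
    order total.
    """
    k = len(q)
    m = scheme.m
    if m > k:
        raise ValueError(f"minimizer length {m} exceeds k-mer length {k}")
    best = None
    for i in range(k - m + 1):
        w = q[i : i + m]
        key = (hash_with_seed(encode_kmer(w), scheme.order_seed), encode_kmer(w))
        if best is None or key < best[0]:
            best = (key, w)
    return best[1]


def minimizers_packed(keys: np.ndarray, k: int, scheme: MinimizerScheme) -> np.ndarray:
    """Vectorized minimizer of each packed k-mer; returns packed m-mers."""
    m = scheme.m
    if m > k:
        raise ValueError(f"minimizer length {m} exceeds k-mer length {k}")
    keys = np.asarray(keys, dtype=np.uint64)
    mask = np.uint64((1 << (2 * m)) - 1)
    best_w = (keys >> np.uint64(2 * (k - m))) & mask
    best_h = hash_with_seed_array(best_w, scheme.order_seed)
    for i in range(1, k - m + 1):
        w = (keys >> np.uint64(2 * (k - m - i))) & mask
        h = hash_with_seed_array(w, scheme.order_seed)
        better = (h < best_h) | ((h == best_h) & (w < best_w))
        best_h = np.where(better, h, best_h)
        best_w = np.where(better, w, best_w)
    return best_w


def group_by_minimizer(
    keys: np.ndarray, values: np.ndarray, k: int, scheme: MinimizerScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Group values by the minimizer of their k-mer.

    Returns ``(minimizers, inverse, min_v, max_v, sizes)`` where
    ``minimizers`` are the distinct packed m-mers (sorted) and ``inverse``
    maps each input key to its bucket index.
    """
    mz = minimizers_packed(keys, k, scheme)
    uniq, inverse = np.unique(mz, return_inverse=True)
    nb = uniq.size
    values = np.asarray(values, dtype=np.int64)
    min_v = np.full(nb, np.iinfo(np.int64).max, dtype=np.int64)
    max_v = np.full(nb, np.iinfo(np.int64).min, dtype=np.int64)
    np.minimum.at(min_v, inverse, values)
    np.maximum.at(max_v, inverse, values)
    sizes = np.bincount(inverse, minlength=nb).astype(np.int64)
    return uniq, inverse, min_v, max_v, sizes


def group_majority(
    keys: np.ndarray, values: np.ndarray, k: int, scheme: MinimizerScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-bucket modal value, ties toward the smallest value.

    Returns ``(minimizers, majority, inverse)`` aligned like
    :func:`group_by_minimizer`.
    """
    mz = minimizers_packed(keys, k, scheme)
    uniq, inverse = np.unique(mz, return_inverse=True)
    values = np.asarray(values, dtype=np.int64)
    vmin = int(values.min())
    span = int(values.max()) - vmin + 1
    # one histogram cell per (bucket, value) pair
    cell = inverse.astype(np.int64) * span + (values - vmin)
    cells, freq = np.unique(cell, return_counts=True)
    bucket_of_cell = cells // span
    value_of_cell = cells % span + vmin
    # cells are sorted, hence grouped by bucket with values ascending; the
    # majority is the first cell of each bucket attaining the max frequency
    best = np.zeros(uniq.size, dtype=np.int64)
    np.maximum.at(best, bucket_of_cell, freq)
    at_max = freq == best[bucket_of_cell]
    winners_b = bucket_of_cell[at_max]
    winners_v = value_of_cell[at_max]
    _, first = np.unique(winners_b, return_index=True)
    majority = winners_v[first]
    return uniq, majority, inverse


def bucket_counts(table, scheme: MinimizerScheme, delta: int = 0) -> dict[str, Bucket]:
    """Bucket a count table by minimizer; see :class:`Bucket` for fields."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    uniq, _, min_v, max_v, sizes = group_by_minimizer(
        table.keys, table.counts, table.k, scheme
    )
    return {
        decode_kmer(int(u), scheme.m): Bucket(
            minimizer=decode_kmer(int(u), scheme.m),
            min_count=int(lo),
            max_count=int(hi),
            size=int(sz),
        )
        for u, lo, hi, sz in zip(uniq, min_v, max_v, sizes)
    }


def bucket_majority(table, scheme: MinimizerScheme) -> dict[str, int]:
    """Exact modal count per minimizer bucket (ties toward the smallest value)."""
    uniq, majority, _ = group_majority(table.keys, table.counts, table.k, scheme)
    return {decode_kmer(int(u), scheme.m): int(v) for u, v in zip(uniq, majority)}
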