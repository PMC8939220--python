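"""Minimizer-bucketed cascades over BCSFs: the AMB and FIL schemes.

Both schemes exploit the locality of minimizers — k-mers sharing a
minimizer usually share a count — to answer most queries from a small
table keyed by m-mers instead of k-mers.

AMB stores, per bucket, its minimum count if the bucket is coherent
(all counts within delta of each other) and the reserved marker 0
otherwise; count 0 never occurs in real tables, so the marker is
unambiguous.  k-mers of marked buckets cascade to the next layer
(longer minimizers, hence finer buckets) and finally to a residual
BCSF keyed by the k-mers themselves.  With delta = 0 answers are exact;
with delta > 0 they are within delta of the truth, because a coherent
bucket's minimum is within delta of every member.

FIL stores, per layer, the per-bucket majority count and keeps every
k-mer in play: layer i's representatives are subtracted from the
running residual, and a final corrections BCSF maps each k-mer to what
is left.  Queries sum all layer representatives plus the correction —
always exact.  Corrections are mostly 0 (the majority rule guarantees
0 is the modal correction), which is exactly the regime where the BCSF
is smallest.  Residuals can be negative, so stored values go through
the zigzag map keeping the alphabet non-negative with 0 dominant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._hash import mix_seeds
from .bcsf import BCSFStructure, build_bcsf
from .kmer_tables import CountTable
from .minimizers import MinimizerScheme, group_by_minimizer, group_majority, minimizers_packed

__all__ = ["AMBStructure", "FILStructure", "build_amb", "amb_query", "build_fil", "fil_query"]

AMBIGUOUS_MARKER = 0


def _zigzag(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.int64)
    return np.where(v >= 0, 2 * v, -2 * v - 1)


def _unzigzag(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.int64)
    return np.where(u % 2 == 0, u // 2, -(u + 1) // 2)


def _check_lengths(minimizer_lengths, k: int) -> list[int]:
    lengths = [int(m) for m in minimizer_lengths]
    if not lengths:
        raise ValueError("need at least one minimizer length")
    if any(m2 <= m1 for m1, m2 in zip(lengths, lengths[1:])):
        raise ValueError(f"minimizer lengths must be strictly increasing: {lengths}")
    if lengths[-1] > k:
        raise ValueError(f"minimizer length {lengths[-1]} exceeds k={k}")
    return lengths


@dataclass
class _Layer:
    scheme: MinimizerScheme
    table: BCSFStructure


@dataclass
class AMBStructure:
    k: int
    delta: int
    layers: list[_Layer]
    residual: BCSFStructure | None
    num_keys: int

    def query_many(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=np.uint64)
        out = np.empty(keys.size, dtype=np.int64)
        pending = np.arange(keys.size)
        for layer in self.layers:
            if pending.size == 0:
                break
            mz = minimizers_packed(keys[pending], self.k, layer.scheme)
            v = layer.table.query_many(mz)
            hit = v != AMBIGUOUS_MARKER
            out[pending[hit]] = v[hit]
            pending = pending[~hit]
        if pending.size:
            if self.residual is None:
                raise KeyError("query cascaded past the last layer with no residual")
            out[pending] = self.residual.query_many(keys[pending])
        return out

    def query(self, key: int) -> int:
        return int(self.query_many(np.array([key], dtype=np.uint64))[0])

    @property
    def payload_bits(self) -> int:
        bits = sum(l.table.payload_bits for l in self.layers)
        if self.residual is not None:
            bits += self.residual.payload_bits
        return bits


@dataclass
class FILStructure:
    k: int
    layers: list[_Layer]
    corrections: BCSFStructure
    num_keys: int

    def query_many(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=np.uint64)
        acc = np.zeros(keys.size, dtype=np.int64)
        for layer in self.layers:
            mz = minimizers_packed(keys, self.k, layer.scheme)
            acc += _unzigzag(layer.table.query_many(mz))
        acc += _unzigzag(self.corrections.query_many(keys))
        return acc

    def query(self, key: int) -> int:
        return int(self.query_many(np.array([key], dtype=np.uint64))[0])

    @property
    def payload_bits(self) -> int:
        return sum(l.table.payload_bits for l in self.layers) + self.corrections.payload_bits


def build_amb(
    table: CountTable,
    minimizer_lengths,
    delta: int = 0,
    seed: int = 0,
) -> AMBStructure:
    """Build the AMB cascade; exact for delta=0, |error| <= delta otherwise."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    lengths = _check_lengths(minimizer_lengths, table.k)
    keys = table.keys
    counts = table.counts.astype(np.int64)
    layers: list[_Layer] = []
    for i, m in enumerate(lengths):
        if keys.size == 0:
            break
        scheme = MinimizerScheme(m, order_seed=mix_seeds(seed, 0x313D, i))
        uniq, inverse, min_v, max_v, _ = group_by_minimizer(keys, counts, table.k, scheme)
        ambiguous = (max_v - min_v) > delta
        bucket_vals = np.where(ambiguous, AMBIGUOUS_MARKER, min_v)
        bcsf = build_bcsf((uniq, bucket_vals), seed=mix_seeds(seed, 0xA3B, i))
        layers.append(_Layer(scheme=scheme, table=bcsf))
        survive = ambiguous[inverse]
        keys, counts = keys[survive], counts[survive]
    residual = None
    if keys.size:
        residual = build_bcsf((keys, counts), seed=mix_seeds(seed, 0x2E5))
    return AMBStructure(
        k=table.k, delta=delta, layers=layers, residual=residual, num_keys=len(table)
    )


def build_fil(
    table: CountTable,
    minimizer_lengths,
    seed: int = 0,
) -> FILStructure:
    """Build the FIL cascade: majority representatives plus corrections."""
    lengths = _check_lengths(minimizer_lengths, table.k)
    keys = table.keys
    residual = table.counts.astype(np.int64)
    layers: list[_Layer] = []
    for i, m in enumerate(lengths):
        scheme = MinimizerScheme(m, order_seed=mix_seeds(seed, 0x313D, i))
        uniq, majority, inverse = group_majority(keys, residual, table.k, scheme)
        bcsf = build_bcsf((uniq, _zigzag(majority)), seed=mix_seeds(seed, 0xF17, i))
        layers.append(_Layer(scheme=scheme, table=bcsf))
        residual = residual - majority[inverse]
    corrections = build_bcsf((keys, _zigzag(residual)), seed=mix_seeds(seed, 0xC02))
    return FILStructure(
        k=table.k, layers=layers, corrections=corrections, num_keys=len(table)
    )


def amb_query(structure: AMBStructure, kmer) -> int:
    """Count of a built k-mer (string or packed int)."""
    return structure.query(_as_key(kmer, structure.k))


def fil_query(structure: FILStructure, kmer) -> int:
    return structure.query(_as_key(kmer, structure.k))


def _as_key(kmer, k: int) -> int:
    if isinstance(kmer, str):
        from ._encoding import encode_kmer

        if len(kmer) != k:
            raise ValueError(f"expected a {k}-mer, got length {len(kmer)}")
        return encode_kmer(kmer)
    return int(kmer)
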