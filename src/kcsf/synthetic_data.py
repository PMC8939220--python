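"""Seeded generators for synthetic genomes and count tables.

These emulate the statistical shape of real k-mer count data — mostly
unique k-mers with a repeat-driven tail in whole genomes, heavy-tailed
(power-law) count spectra, and a tunable dominant-value fraction alpha
— without requiring any download.  Everything is deterministic under a
fixed seed, and every table satisfies the CountTable invariants
(distinct keys, counts >= 1).
"""

from __future__ import annotations

import numpy as np

from ._encoding import MAX_K
from .kmer_tables import CountTable

__all__ = ["random_genome", "powerlaw_table", "dominant_table", "shred_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(
    length_bp: int,
    repeat_fraction: float = 0.0,
    repeat_unit_bp: int = 500,
    seed: int = 0,
) -> str:
    """A random genome with a controllable repeat content.

    Bases are i.i.d. uniform except that ~``repeat_fraction`` of the
    sequence consists of copies of earlier segments of length
    ``repeat_unit_bp``, so k-mers inside repeated units occur at least
    twice (for k <= unit length).
    """
    if not 0.0 <= repeat_fraction < 1.0:
        raise ValueError("repeat_fraction must be in [0, 1)")
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(length_bp, dtype=np.uint8)
    pos = 0
    # lay down an initial unique stretch so repeats have a source
    head = min(length_bp, max(repeat_unit_bp, int(length_bp * (1 - repeat_fraction) * 0.1) or 1))
    out[:head] = _BASES[rng.integers(0, 4, size=head)]
    pos = head
    while pos < length_bp:
        unit = min(repeat_unit_bp, length_bp - pos)
        if repeat_fraction > 0.0 and rng.random() < repeat_fraction:
            src = int(rng.integers(0, pos - unit + 1)) if pos > unit else 0
            out[pos : pos + unit] = out[src : src + unit]
        else:
            out[pos : pos + unit] = _BASES[rng.integers(0, 4, size=unit)]
        pos += unit
    return out.tobytes().decode("ascii")


def _random_distinct_kmers(n_keys: int, k: int, rng: np.random.Generator) -> np.ndarray:
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    space = 4**k
    if n_keys > space:
        raise ValueError(f"cannot draw {n_keys} distinct {k}-mers from a space of {space}")
    if space <= 4 * n_keys:
        # dense regime: permute the whole space
        keys = rng.permutation(space)[:n_keys].astype(np.uint64)
        return np.sort(keys)
    keys = np.unique(rng.integers(0, space, size=int(n_keys * 1.2) + 16, dtype=np.uint64))
    while keys.size < n_keys:
        extra = rng.integers(0, space, size=n_keys, dtype=np.uint64)
        keys = np.unique(np.concatenate([keys, extra]))
    rng.shuffle(keys)  # drop the surplus uniformly, not by magnitude
    return np.sort(keys[:n_keys].copy())


def powerlaw_table(
    n_keys: int,
    exponent: float = 2.5,
    max_count: int = 100,
    k: int = 21,
    seed: int = 0,
) -> CountTable:
    """Counts with P(c) proportional to c^-exponent, truncated at max_count.

    Sampling is by inverse CDF over the truncated support {1..max_count},
    mirroring the heavy-tailed spectra of real k-mer data where most
    k-mers occur once.  ``max_count=1`` degenerates to an all-ones table.
    """
    if exponent <= 1.0:
        raise ValueError("exponent must be > 1")
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    rng = np.random.default_rng(seed)
    keys = _random_distinct_kmers(n_keys, k, rng)
    support = np.arange(1, max_count + 1, dtype=np.float64)
    pmf = support**-exponent
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random(n_keys)
    counts = (np.searchsorted(cdf, u, side="right") + 1).astype(np.int64)
    counts = np.minimum(counts, max_count)
    return CountTable(k=k, keys=keys, counts=counts)


def dominant_table(
    n_keys: int,
    alpha: float,
    v0: int = 1,
    other_values: dict[int, int] | None = None,
    k: int = 21,
    seed: int = 0,
) -> CountTable:
    """A table in which a fraction ``alpha`` of keys carries the value v0.

    The remaining keys draw from ``other_values`` (a value->weight
    histogram, default {v0+1: 2, v0+2: 1, v0+3: 1}); the realized alpha
    is within 1/n_keys of the request.  Direct control of alpha makes
    this the natural fixture for the Bloom-dimensioning threshold.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if v0 < 1:
        raise ValueError("v0 must be >= 1 (counts are positive)")
    rng = np.random.default_rng(seed)
    keys = _random_distinct_kmers(n_keys, k, rng)
    n0 = round(alpha * n_keys)
    counts = np.full(n_keys, v0, dtype=np.int64)
    n_rest = n_keys - n0
    if n_rest > 0:
        if other_values is None:
            other_values = {v0 + 1: 2, v0 + 2: 1, v0 + 3: 1}
        if any(v < 1 for v in other_values):
            raise ValueError("other_values must be positive counts")
        vals = np.array(sorted(other_values), dtype=np.int64)
        w = np.array([other_values[int(v)] for v in vals], dtype=np.float64)
        drawn = rng.choice(vals, size=n_rest, p=w / w.sum())
        where = rng.choice(n_keys, size=n_rest, replace=False)
        counts[where] = drawn
    return CountTable(k=k, keys=keys, counts=counts)


def shred_reads(
    genome: str,
    read_length: int = 100,
    coverage: float = 10.0,
    seed: int = 0,
) -> list[str]:
    """Uniform-coverage reads from a genome (no error model).

    A simple shredder for producing higher-entropy count tables like
    those of unassembled sequencing runs.
    """
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * len(genome) / read_length))
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    return [genome[s : s + read_length] for s in starts]
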