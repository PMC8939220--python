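"""Entropy, dominance, size accounting, and minimizer-length heuristics.

The zero-order empirical entropy of a count table,

    H0(f) = sum_l (|f^-1(l)| / |K|) * log2(|K| / |f^-1(l)|),

is the information-theoretic floor, in bits per key, for storing the
counts without structural assumptions; the compression structures in
this package are judged against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "entropy_h0",
    "dominant_fraction",
    "bits_per_kmer",
    "suggest_minimizer_lengths",
    "sequential_length_search",
    "LengthSuggestion",
]


def _histogram_of(table_or_histogram) -> dict[int, int]:
    if isinstance(table_or_histogram, dict):
        if not table_or_histogram:
            raise ValueError("empty histogram")
        if any(m <= 0 for m in table_or_histogram.values()):
            raise ValueError("histogram multiplicities must be positive")
        return table_or_histogram
    return table_or_histogram.value_histogram()


def entropy_h0(table_or_histogram) -> float:
    """Zero-order empirical entropy of the value multiset, in bits."""
    hist = _histogram_of(table_or_histogram)
    n = sum(hist.values())
    h0 = sum((m / n) * math.log2(n / m) for m in hist.values())
    return max(0.0, h0)


def dominant_fraction(table_or_histogram) -> tuple[int, float]:
    """Modal count value and its key fraction; ties toward the smaller value."""
    hist = _histogram_of(table_or_histogram)
    n = sum(hist.values())
    v0 = min(hist, key=lambda v: (-hist[v], v))
    return int(v0), hist[v0] / n


def bits_per_kmer(structure, num_keys: int | None = None) -> dict[str, float]:
    """Serialized size per key with a per-component breakdown.

    The breakdown keys are the container's sections plus ``header``;
    components sum to ``total``.  ``num_keys`` defaults to the
    structure's own key count.
    """
    from .serialization import dumps, inspect

    n = num_keys if num_keys is not None else structure.num_keys
    if n <= 0:
        raise ValueError("num_keys must be positive")
    info = inspect(dumps(structure))
    out = {name: 8.0 * size / n for name, size in info["sections"].items()}
    out["header"] = 8.0 * info["header_bytes"] / n
    out["total"] = 8.0 * info["total_bytes"] / n
    return out


@dataclass
class LengthSuggestion:
    """Outcome of the minimizer-length rule for a genome of |G| bases."""

    m_s: float  # log4(|G|) + 2, the smallest useful first-layer length
    candidates: list[int]  # integer lengths in the open interval (m_s, k)
    mode: str  # "exact", "approximate", or "plain"
    approximate_lengths: tuple[int, ...] = ()


def suggest_minimizer_lengths(genome_size_bp: int, k: int) -> LengthSuggestion:
    """First-layer minimizer lengths worth trying for a |G|-base genome.

    Below ``m_s = log4(|G|) + 2`` minimizers no longer partition k-mers
    meaningfully.  When no integer fits strictly between m_s and k, the
    fallback is the approximate cascade with layers at k-2 and k-1; for
    degenerate k there is nothing to bucket and a plain BCSF is the
    recommendation.
    """
    if genome_size_bp < 1:
        raise ValueError("genome size must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    m_s = math.log(genome_size_bp, 4) + 2
    candidates = [m for m in range(math.floor(m_s) + 1, k) if m > m_s]
    if candidates:
        return LengthSuggestion(m_s=m_s, candidates=candidates, mode="exact")
    if k <= 2:
        return LengthSuggestion(m_s=m_s, candidates=[], mode="plain")
    return LengthSuggestion(
        m_s=m_s,
        candidates=[],
        mode="approximate",
        approximate_lengths=(k - 2, k - 1),
    )


def sequential_length_search(
    table,
    candidates,
    seed: int = 0,
    delta: int = 0,
    scheme: str = "amb",
) -> tuple[int | None, dict[int, float]]:
    """Try candidate first-layer lengths in order; stop when size grows.

    Builds a real single-layer cascade per candidate and compares
    serialized bits per key.  Compressed size is empirically unimodal in
    the minimizer length, so the search stops at the first increase.
    Returns (best length or None, sizes measured).
    """
    from .layered_schemes import build_amb, build_fil

    sizes: dict[int, float] = {}
    best_m = None
    best_size = math.inf
    for m in candidates:
        if scheme == "amb":
            s = build_amb(table, [m], delta=delta, seed=seed)
        elif scheme == "fil":
            s = build_fil(table, [m], seed=seed)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        size = bits_per_kmer(s)["total"]
        sizes[m] = size
        if size < best_size:
            best_m, best_size = m, size
        elif size > best_size:
            break
    return best_m, sizes
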