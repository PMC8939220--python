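"""Bloom-enhanced compressed static function (BCSF).

A plain CSF cannot go below ~1 bit per key once the value alphabet has
two or more symbols, yet whole-genome k-mer count tables are dominated
by a single value (count 1, typically carried by ~97% of distinct
k-mers).  The fix: store the *non-dominant* keys in a Bloom filter and
build the CSF only on the filter's positives.  A Bloom-negative key is
guaranteed dominant (no false negatives), so it costs only the filter
probe; false positives among dominant keys are stored in the CSF with
the dominant value, so every query stays exact.

Whether the filter pays off, and at which false-positive rate, follows
from the cost model: with C_BF bits per key per log2(1/eps) for the
filter and C_CSF bits per key for the CSF, total space is minimized at

    eps0 = (C_BF / C_CSF) * ((1 - alpha) / alpha) * log2(e),

and the filter saves space exactly when eps0 < 1, i.e. when the
dominant fraction alpha exceeds C_BF*log2(e) / (C_CSF + C_BF*log2(e))
— about 0.59 when the two coefficients are equal.  C_CSF itself is
estimated from the empirical entropy H0 by a fitted envelope:
0.22*H0^2 + 0.18*H0 + 1.16 below H0 = 2, else 1.1*H0 + 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._hash import mix_seeds
from .bloom_filter import LOG2_E, BloomFilter, build_bloom
from .csf_core import DEFAULT_GAMMA, CSFStructure, build_csf

__all__ = [
    "EntropyStats",
    "CostModel",
    "BCSFStructure",
    "entropy_stats",
    "estimate_c_csf",
    "optimal_epsilon",
    "build_bcsf",
    "bcsf_query",
]

C_BF_DEFAULT = 1.44  # bits per key per log2(1/eps), the Bloom filter optimum


@dataclass
class EntropyStats:
    """Value histogram of a table with its entropy and dominance summary."""

    histogram: dict[int, int]
    H0: float
    dominant_value: int
    alpha: float
    num_keys: int

    @classmethod
    def from_values(cls, values: np.ndarray) -> "EntropyStats":
        values = np.asarray(values, dtype=np.int64)
        if values.size == 0:
            raise ValueError("empty value array")
        vals, mult = np.unique(values, return_counts=True)
        n = int(values.size)
        p = mult / n
        h0 = float(-(p * np.log2(p)).sum())
        # modal value; ties toward the smaller value (vals is sorted)
        top = int(np.argmax(mult))
        return cls(
            histogram={int(v): int(m) for v, m in zip(vals, mult)},
            H0=max(0.0, h0),
            dominant_value=int(vals[top]),
            alpha=float(mult[top] / n),
            num_keys=n,
        )


def entropy_stats(table_or_values) -> EntropyStats:
    """EntropyStats from a CountTable or a raw value array."""
    values = getattr(table_or_values, "counts", table_or_values)
    return EntropyStats.from_values(np.asarray(values))


def estimate_c_csf(h0: float) -> float:
    """Fitted CSF cost envelope, bits per key, as a function of H0.

    Quadratic below the kink at H0 = 2, linear above; the two branches
    agree at the kink (both give 2.4).
    """
    if h0 < 0:
        raise ValueError(f"H0 must be >= 0, got {h0}")
    if h0 < 2.0:
        return 0.22 * h0 * h0 + 0.18 * h0 + 1.16
    return 1.1 * h0 + 0.2


@dataclass
class CostModel:
    """Per-key cost coefficients driving the Bloom dimensioning."""

    c_bf: float = C_BF_DEFAULT
    c_csf: float = 1.16

    def __post_init__(self) -> None:
        if self.c_bf <= 0:
            raise ValueError("c_bf must be positive")
        if self.c_csf < 1.0:
            raise ValueError("c_csf must be >= 1 (the CSF per-key floor)")

    @classmethod
    def from_entropy(cls, h0: float, c_bf: float = C_BF_DEFAULT) -> "CostModel":
        return cls(c_bf=c_bf, c_csf=max(1.0, estimate_c_csf(h0)))


def optimal_epsilon(
    alpha: float, c_bf: float = C_BF_DEFAULT, c_csf: float = 1.16
) -> tuple[float, bool]:
    """Optimal Bloom FP rate eps0 and whether a filter saves space.

    eps0 minimizes (c_bf/c_csf)*((1-alpha)/alpha)*log2(1/eps) + eps, the
    per-key space in units of c_csf; a filter helps iff eps0 < 1.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha == 1.0:
        return 0.0, False  # no non-dominant keys: nothing to filter
    eps0 = (c_bf / c_csf) * ((1.0 - alpha) / alpha) * LOG2_E
    return eps0, eps0 < 1.0


def bloom_threshold_alpha(c_bf: float = C_BF_DEFAULT, c_csf: float = 1.16) -> float:
    """The dominant fraction above which a Bloom filter saves space."""
    return c_bf * LOG2_E / (c_csf + c_bf * LOG2_E)


@dataclass
class BCSFStructure:
    """Optional Bloom filter in front of a CSF; exact for every built key."""

    dominant_value: int
    num_keys: int
    epsilon: float | None = None
    bloom: BloomFilter | None = None
    csf: CSFStructure | None = None
    stats: EntropyStats = field(default=None, repr=False)

    def query_many(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=np.uint64)
        if self.csf is None:  # alpha == 1: pure constant
            return np.full(keys.size, self.dominant_value, dtype=np.int64)
        if self.bloom is None:
            return self.csf.query_many(keys)
        out = np.full(keys.size, self.dominant_value, dtype=np.int64)
        pos = self.bloom.query_many(keys)
        if pos.any():
            out[pos] = self.csf.query_many(keys[pos])
        return out

    def query(self, key: int) -> int:
        return int(self.query_many(np.array([key], dtype=np.uint64))[0])

    @property
    def payload_bits(self) -> int:
        bits = 0
        if self.bloom is not None:
            bits += self.bloom.payload_bits
        if self.csf is not None:
            bits += self.csf.payload_bits
        return bits

    def size_breakdown(self) -> dict[str, int]:
        return {
            "bloom_bits": self.bloom.payload_bits if self.bloom else 0,
            "csf_bits": self.csf.payload_bits if self.csf else 0,
        }


def build_bcsf(
    pairs,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
    cost_model: CostModel | None = None,
    force_bloomless: bool = False,
) -> BCSFStructure:
    """Build a BCSF, deciding the Bloom stage analytically.

    ``pairs`` is a dict key->value or a (keys, values) array pair, keys
    being packed integers.  ``cost_model`` overrides the fitted C_CSF /
    C_BF coefficients; ``force_bloomless`` builds the plain-CSF variant
    regardless of the dimensioning rule (used for comparisons).
    """
    keys, values = _as_arrays(pairs)
    if keys.size == 0:
        raise ValueError("empty input")
    stats = EntropyStats.from_values(values)
    v0 = stats.dominant_value

    if stats.alpha == 1.0:
        return BCSFStructure(
            dominant_value=v0, num_keys=stats.num_keys, stats=stats
        )

    model = cost_model or CostModel.from_entropy(stats.H0)
    eps0, use_bloom = optimal_epsilon(stats.alpha, model.c_bf, model.c_csf)

    if force_bloomless or not use_bloom:
        csf = build_csf((keys, values), gamma=gamma, seed=mix_seeds(seed, 0xC5F))
        return BCSFStructure(
            dominant_value=v0, num_keys=stats.num_keys, csf=csf, stats=stats
        )

    dominant = values == v0
    others = keys[~dominant]
    bloom = build_bloom(others, eps0, seed=mix_seeds(seed, 0xB1))
    fp = keys[dominant][bloom.query_many(keys[dominant])]
    csf_keys = np.concatenate([others, fp])
    csf_vals = np.concatenate(
        [values[~dominant], np.full(fp.size, v0, dtype=np.int64)]
    )
    csf = build_csf((csf_keys, csf_vals), gamma=gamma, seed=mix_seeds(seed, 0xC5F))
    return BCSFStructure(
        dominant_value=v0,
        num_keys=stats.num_keys,
        epsilon=eps0,
        bloom=bloom,
        csf=csf,
        stats=stats,
    )


def bcsf_query(structure: BCSFStructure, key: int) -> int:
    return structure.query(key)


def _as_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, dict):
        keys = np.array([int(k) for k in pairs], dtype=np.uint64)
        values = np.array([int(v) for v in pairs.values()], dtype=np.int64)
        return keys, values
    keys, values = pairs
    return np.asarray(keys, dtype=np.uint64), np.asarray(values, dtype=np.int64)
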