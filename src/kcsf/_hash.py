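"""64-bit non-cryptographic hashing used throughout the package.

All randomized components (minimizer orders, Bloom filters, CSF chunk
seeds) are driven by the splitmix64 finalizer, which passes standard
avalanche tests and is trivially reproducible across platforms.  Scalar
and numpy-vectorized variants share the same constants, so a value hashed
one key at a time equals the same key hashed in bulk.
"""

from __future__ import annotations

import numpy as np

_MASK64 = (1 << 64) - 1

_C1 = 0xBF58476D1CE4E5B9
_C2 = 0x94D049BB133111EB
_GAMMA = 0x9E3779B97F4A7C15


def splitmix64(x: int) -> int:
    """Finalize a 64-bit value into a well-mixed 64-bit hash."""
    x = (x + _GAMMA) & _MASK64
    x ^= x >> 30
    x = (x * _C1) & _MASK64
    x ^= x >> 27
    x = (x * _C2) & _MASK64
    return x ^ (x >> 31)


def splitmix64_array(x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`splitmix64` over a uint64 array (wrapping arithmetic)."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(_GAMMA)
    x ^= x >> np.uint64(30)
    x *= np.uint64(_C1)
    x ^= x >> np.uint64(27)
    x *= np.uint64(_C2)
    x ^= x >> np.uint64(31)
    return x


def hash_with_seed(key: int, seed: int) -> int:
    return splitmix64(key ^ splitmix64(seed))


def hash_with_seed_array(keys: np.ndarray, seed: int) -> np.ndarray:
    return splitmix64_array(keys ^ np.uint64(splitmix64(seed)))


def mix_seeds(*parts: int) -> int:
    """Derive a child seed deterministically from integer parts."""
    acc = 0x8000000000000000
    for p in parts:
        acc = splitmix64(acc ^ (p & _MASK64))
    return acc
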