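"""Shared fixtures: small deterministic tables and genomes."""

from __future__ import annotations

import numpy as np
import pytest

from kcsf.kmer_tables import CountTable, count_kmers
from kcsf.synthetic_data import dominant_table, powerlaw_table, random_genome


@pytest.fixture(scope="session")
def small_table() -> CountTable:
    """10^4 random 21-mers, skewed 3-value counts."""
    return dominant_table(
        10_000, alpha=0.9, v0=1, other_values={2: 3, 3: 1}, k=21, seed=11
    )


@pytest.fixture(scope="session")
def highentropy_table() -> CountTable:
    """10^4 random 21-mers with a heavy-tailed count spectrum."""
    return powerlaw_table(10_000, exponent=1.5, max_count=60, k=21, seed=13)


@pytest.fixture(scope="session")
def genome_table() -> CountTable:
    """Counts of an actual (synthetic) genome so minimizer locality is real."""
    g = random_genome(100_000, repeat_fraction=0.1, repeat_unit_bp=300, seed=17)
    return count_kmers([g], 18)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
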