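"""k-mer count tables: counting, document frequency, and TSV dump I/O.

The central object is :class:`CountTable`, a static associative array
from canonical k-mers to positive integer counts — the map ``f`` that the
compression structures in this package represent.  Keys are held as
2-bit-packed uint64 arrays (k <= 31) so that downstream hashing and
minimizer computations are vectorized.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from ._encoding import (
    MAX_K,
    canonical_packed,
    decode_kmer,
    encode_kmer,
    packed_windows,
    revcomp_windows,
    sequence_to_codes,
)

__all__ = [
    "CountTable",
    "count_kmers",
    "document_frequency",
    "read_count_table",
    "write_count_table",
    "read_sequences",
]


@dataclass
class CountTable:
    """Static map from distinct k-mers to counts >= 1.

    ``keys`` are packed canonical k-mers, sorted ascending; ``counts``
    align with ``keys``.  Count 0 is reserved (absent k-mers), so every
    stored count is at least 1.
    """

    k: int
    keys: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        self.keys = np.asarray(self.keys, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.keys.shape != self.counts.shape:
            raise ValueError("keys and counts must align")
        if self.keys.size == 0:
            raise ValueError("empty count table")
        if self.keys.size > 1 and not (self.keys[1:] > self.keys[:-1]).all():
            order = np.argsort(self.keys)
            self.keys = self.keys[order]
            self.counts = self.counts[order]
            if (self.keys[1:] == self.keys[:-1]).any():
                raise ValueError("duplicate k-mer keys")
        if (self.counts < 1).any():
            raise ValueError("all counts must be >= 1 (0 is reserved)")
        if self.keys.size and int(self.keys.max()) >= 4**self.k:
            raise ValueError("packed key exceeds 2k bits; wrong k?")

    @classmethod
    def from_dict(cls, entries: Mapping[str, int], k: int | None = None) -> "CountTable":
        if not entries:
            raise ValueError("empty count table")
        kmers = list(entries)
        if k is None:
            k = len(kmers[0])
        for q in kmers:
            if len(q) != k:
                raise ValueError(f"key {q!r} has length {len(q)}, expected {k}")
        keys = np.array([encode_kmer(q) for q in kmers], dtype=np.uint64)
        counts = np.array([entries[q] for q in kmers], dtype=np.int64)
        return cls(k=k, keys=keys, counts=counts)

    def to_dict(self) -> dict[str, int]:
        return {decode_kmer(int(q), self.k): int(c) for q, c in zip(self.keys, self.counts)}

    def __len__(self) -> int:
        return int(self.keys.size)

    def __contains__(self, kmer: str) -> bool:
        packed = np.uint64(encode_kmer(kmer))
        i = int(np.searchsorted(self.keys, packed))
        return i < len(self) and self.keys[i] == packed

    def __getitem__(self, kmer: str) -> int:
        packed = np.uint64(encode_kmer(kmer))
        i = int(np.searchsorted(self.keys, packed))
        if i >= len(self) or self.keys[i] != packed:
            raise KeyError(kmer)
        return int(self.counts[i])

    def items(self) -> Iterator[tuple[str, int]]:
        for q, c in zip(self.keys, self.counts):
            yield decode_kmer(int(q), self.k), int(c)

    @property
    def total_count(self) -> int:
        """L1 norm of the table (sum of all counts)."""
        return int(self.counts.sum())

    def value_histogram(self) -> dict[int, int]:
        """Multiplicity of each distinct count value."""
        vals, mult = np.unique(self.counts, return_counts=True)
        return {int(v): int(m) for v, m in zip(vals, mult)}


def _canonical_window_arrays(
    seq: str, k: int, canonical: bool
) -> tuple[np.ndarray, np.ndarray]:
    codes = sequence_to_codes(seq)
    fwd, valid = packed_windows(codes, k)
    if fwd.size == 0:
        return fwd, valid
    if canonical:
        rc = revcomp_windows(codes, k)
        fwd = np.minimum(fwd, rc)
    return fwd, valid


def count_kmers(
    sequences: Iterable[str], k: int, *, canonical: bool = True
) -> CountTable:
    """Count canonical k-mers over a collection of DNA sequences.

    Windows containing N are skipped; lowercase input is accepted.  With
    ``canonical=False`` the forward strand is counted as-is.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    chunks = []
    saw_sequence = False
    for seq in sequences:
        saw_sequence = True
        packed, valid = _canonical_window_arrays(seq, k, canonical)
        if packed.size:
            chunks.append(packed[valid])
    if not saw_sequence:
        raise ValueError("no input sequences")
    if not chunks or sum(c.size for c in chunks) == 0:
        raise ValueError(f"no valid windows of length k={k} in the input")
    allk = np.concatenate(chunks)
    keys, counts = np.unique(allk, return_counts=True)
    return CountTable(k=k, keys=keys, counts=counts.astype(np.int64))


def document_frequency(
    genomes: Iterable[Iterable[str]], k: int, *, canonical: bool = True
) -> CountTable:
    """Per-k-mer document frequency across a list of genomes.

    Each distinct canonical k-mer maps to the number of genomes that
    contain it at least once, so all counts lie in [1, n_genomes].
    """
    per_genome: list[np.ndarray] = []
    for genome in genomes:
        chunks = []
        for seq in genome:
            packed, valid = _canonical_window_arrays(seq, k, canonical)
            if packed.size:
                chunks.append(packed[valid])
        if not chunks:
            raise ValueError("genome with no valid k-windows")
        per_genome.append(np.unique(np.concatenate(chunks)))
    if not per_genome:
        raise ValueError("no input genomes")
    allk = np.concatenate(per_genome)
    keys, counts = np.unique(allk, return_counts=True)
    return CountTable(k=k, keys=keys, counts=counts.astype(np.int64))


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write the two-column dump format ``<KMER>\\t<COUNT>``."""
    with open(path, "w") as fh:
        for kmer, count in table.items():
            fh.write(f"{kmer}\t{count}\n")


def read_count_table(path: str | Path) -> CountTable:
    """Read a two-column TSV dump; k is inferred from the first record."""
    kmers: list[int] = []
    counts: list[int] = []
    k = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            kmer, count_s = parts
            if k is None:
                k = len(kmer)
                if k > MAX_K:
                    raise ValueError(
                        f"{path}:{lineno}: k={k} exceeds the supported maximum {MAX_K}"
                    )
            elif len(kmer) != k:
                raise ValueError(
                    f"{path}:{lineno}: key length {len(kmer)} != inferred k={k}"
                )
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad count {count_s!r}") from None
            if count < 1:
                raise ValueError(f"{path}:{lineno}: counts must be >= 1, got {count}")
            try:
                kmers.append(encode_kmer(kmer))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            counts.append(count)
    if k is None:
        raise ValueError(f"{path}: empty count table file")
    keys = np.array(kmers, dtype=np.uint64)
    if np.unique(keys).size != keys.size:
        raise ValueError(f"{path}: duplicate k-mer keys")
    return CountTable(k=k, keys=keys, counts=np.array(counts, dtype=np.int64))


def read_sequences(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ, plain or gzipped."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with opener(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, fmt)]
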