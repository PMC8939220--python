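"""Counting, document frequency and the TSV dump format."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kcsf._encoding import decode_kmer, encode_kmer, revcomp_packed
from kcsf.kmer_tables import (
    CountTable,
    count_kmers,
    document_frequency,
    read_count_table,
    write_count_table,
)
from kcsf.synthetic_data import random_genome

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)


def revcomp(s: str) -> str:
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestCountKmers:
    @pytest.mark.parametrize(
        "seqs, k, expected",
        [
            (["AAAA"], 3, {"AAA": 2}),
            (["ACGT"], 4, {"ACGT": 1}),  # its own reverse complement
            # windows ACGT,CGTA,GTAC,TACG,ACGT canonicalize to
            # ACGT,CGTA,GTAC,CGTA,ACGT
            (["ACGTACGT"], 4, {"ACGT": 2, "CGTA": 2, "GTAC": 1}),
        ],
    )
    def test_examples(self, seqs, k, expected):
        assert count_kmers(seqs, k).to_dict() == expected

    def test_window_conservation(self):
        g = random_genome(5000, seed=1)
        k = 9
        table = count_kmers([g], k)
        assert table.total_count == len(g) - k + 1

    def test_n_windows_skipped(self):
        table = count_kmers(["ACGTNACGT"], 4)
        # only the two N-free flanks contribute, one window each... each
        # flank ACGT has exactly one 4-window
        assert table.total_count == 2

    def test_lowercase_normalized(self):
        assert count_kmers(["acgt"], 4).to_dict() == count_kmers(["ACGT"], 4).to_dict()

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid character"):
            count_kmers(["ACGX"], 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            count_kmers([], 3)

    def test_k_larger_than_sequences(self):
        with pytest.raises(ValueError, match="no valid windows"):
            count_kmers(["ACGT"], 10)

    def test_k_over_31_rejected(self):
        with pytest.raises(ValueError, match="31"):
            count_kmers(["A" * 40], 32)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=6, max_size=80))
    def test_reverse_complement_invariance(self, seq):
        k = 5
        fwd = count_kmers([seq], k).to_dict()
        rev = count_kmers([revcomp(seq)], k).to_dict()
        assert fwd == rev

    def test_noncanonical_mode(self):
        table = count_kmers(["TTTT"], 3, canonical=False)
        assert table.to_dict() == {"TTT": 2}
        assert count_kmers(["TTTT"], 3).to_dict() == {"AAA": 2}


class TestDocumentFrequency:
    def test_shared_and_private(self):
        assert document_frequency([["ACGTT"], ["ACGTT"]], 5).to_dict() == {
            min("ACGTT", revcomp("ACGTT")): 2
        }
        assert document_frequency([["AAAAA"]], 5).to_dict() == {"AAAAA": 1}

    def test_shared_segment_counts_equal_num_genomes(self):
        # three genomes share a seeded 1 kb segment; a brute-force
        # membership oracle defines the expected document frequencies
        k = 15
        shared = random_genome(1000, seed=99)
        genomes = [
            random_genome(5000, seed=i) + shared + random_genome(5000, seed=100 + i)
            for i in range(3)
        ]
        table = document_frequency([[g] for g in genomes], k)

        def canon_set(g: str) -> set[str]:
            return {
                min(g[i : i + k], revcomp(g[i : i + k])) for i in range(len(g) - k + 1)
            }

        sets = [canon_set(g) for g in genomes]
        oracle = {}
        for s in sets:
            for q in s:
                oracle[q] = oracle.get(q, 0) + 1
        assert table.to_dict() == oracle
        for i in range(len(shared) - k + 1):
            q = min(shared[i : i + k], revcomp(shared[i : i + k]))
            assert table[q] == 3

    def test_counts_bounded_by_num_genomes(self):
        genomes = [[random_genome(2000, seed=i)] for i in range(4)]
        table = document_frequency(genomes, 11)
        assert table.counts.max() <= 4


class TestTSVRoundTrip:
    def test_simple_record(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("AAA\t2\n")
        assert read_count_table(p).to_dict() == {"AAA": 2}

    def test_round_trip_random_table(self, tmp_path, rng):
        keys = rng.choice(4**10, size=1000, replace=False).astype(np.uint64)
        counts = rng.integers(1, 50, size=1000)
        table = CountTable(k=10, keys=keys, counts=counts)
        p = tmp_path / "t.tsv"
        write_count_table(table, p)
        back = read_count_table(p)
        assert back.k == table.k
        assert back.to_dict() == table.to_dict()

    @pytest.mark.parametrize(
        "content, match",
        [
            ("AAA\t0\n", "counts must be >= 1"),
            ("AAA\t2\nACGT\t1\n", "length"),
            ("AAA\n", "2 tab-separated"),
            ("AAA\tx\n", "bad count"),
        ],
    )
    def test_parse_errors_carry_line_numbers(self, tmp_path, content, match):
        p = tmp_path / "bad.tsv"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_count_table(p)


class TestPackedEncoding:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(kmer=st.text(alphabet="ACGT", min_size=1, max_size=31))
    def test_encode_decode_revcomp(self, kmer):
        packed = encode_kmer(kmer)
        assert decode_kmer(packed, len(kmer)) == kmer
        assert decode_kmer(revcomp_packed(packed, len(kmer)), len(kmer)) == revcomp(kmer)
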