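# kcsf — space-efficient, randomly-accessible k-mer count tables

Many sequence-analysis pipelines need the answer to one question, billions of
times: *how often does this k-mer occur in my dataset?*  k-mer counters (KMC,
Jellyfish, ...) produce the raw tables, but their dumps store both k-mers and
counts — tens of gigabytes for a mammalian genome — and support no efficient
random access.  `kcsf` stores only the **values** of the map `f: K → ℕ` from a
static k-mer set to its counts, queryable in O(1), in space close to (and for
large k, *below*) the zero-order empirical entropy of the counts

&nbsp;&nbsp;&nbsp;&nbsp;H₀(f) = Σ_ℓ (|f⁻¹(ℓ)|/|K|) · log₂(|K|/|f⁻¹(ℓ)|).

As with any static function, only k-mers present at build time may be queried;
that is the standard contract under which such structures replace an MPHF +
value array.

Four structures are provided, each building on the previous:

- **CSF** — a compressed static function: each key is assigned three
  pseudo-random windows in a bit array whose XOR equals the codeword of its
  value under a canonical prefix code; building solves the induced linear
  system over GF(2) by hypergraph peeling plus Gaussian elimination on the
  2-core, at a configurable expansion factor γ (default 1.10) over the coded
  size.  Queries XOR three windows and decode a prefix.
- **BCSF** — a Bloom filter over the *non-dominant* keys in front of the CSF.
  Whole-genome count spectra are extremely skewed (typically ~97% of distinct
  k-mers occur once), and a prefix-coded CSF can never beat 1 bit/key; the
  filter lets dominant keys cost only a probe.  The filter's false-positive
  rate is set analytically: with filter cost C_BF·log₂(1/ε) and CSF cost
  C_CSF bits/key, total space is minimized at
  ε₀ = (C_BF/C_CSF)·((1−α)/α)·log₂e, and the filter is worth having exactly
  when the dominant fraction α exceeds C_BF·log₂e/(C_CSF + C_BF·log₂e) ≈ 0.59
  at equal costs.  False positives are stored in the CSF with the dominant
  value, so every query remains exact.
- **AMB** — buckets count values by the hash-ordered **minimizer** of their
  k-mer.  Nearby k-mers share minimizers and usually counts, so most buckets
  hold a single value (or values within a tolerance δ): those buckets store
  their minimum; colliding buckets store the reserved marker 0 and their
  k-mers cascade to a layer of longer minimizers, finally to a k-mer-keyed
  residual BCSF.  Exact at δ = 0; |error| ≤ δ otherwise.
- **FIL** — same bucketing, but every bucket stores its majority value and a
  per-k-mer correction h(q) = f(q) − Σᵢ gᵢ(μ_{mᵢ}(q)) is kept for all keys
  (mostly 0, hence cheap).  Always exact; queries visit all layers.

All tables, bucket layers and correction maps are themselves stored as BCSFs.

## Worked example

```python
from kcsf import (build_amb, build_bcsf, build_fil, count_kmers,
                  suggest_minimizer_lengths)
from kcsf.metrics import bits_per_kmer, dominant_fraction, entropy_h0
from kcsf.synthetic_data import random_genome

g = random_genome(1_000_000, repeat_fraction=0.05, repeat_unit_bp=500, seed=1)
table = count_kmers([g], 18)
print(len(table), dominant_fraction(table), entropy_h0(table))

bcsf = build_bcsf((table.keys, table.counts), seed=7)
amb = build_amb(table, [12, 14], delta=0, seed=7)
print(bits_per_kmer(bcsf)["total"], bits_per_kmer(amb)["total"])
```

On this 1 Mbp synthetic genome the run prints:

```
distinct 18-mers: 951,107
dominant count v0=1, alpha=0.9531, H0=0.2950 bits
BCSF: eps0=0.0830, total=0.455 bits/k-mer
plain CSF: 1.238 bits/k-mer
AMB 12,14: 0.200 bits/k-mer, exact=True
FIL 12: 0.224 bits/k-mer, exact=True
m_s=11.97, candidates=[12, 13, 14, 15, 16, 17]
```

Reading: 95.3% of distinct 18-mers occur once, so the count multiset has only
H₀ = 0.295 bits/key of information.  A plain CSF is stuck at 1.24 bits/k-mer
(the ≥1-bit coding floor plus γ); the Bloom-enhanced build reaches 0.455; and
the two-layer minimizer cascade reaches **0.200 bits/k-mer — below the
empirical entropy**, which no per-key value code can do, by exploiting that
equal counts cluster under shared minimizers.  Queries on all 951,107 built
k-mers return the exact count.  The last line is the first-layer length rule
m₀ > m_s = log₄|G| + 2 for this genome size.

## Command line

```bash
kcsf count --fasta genome.fa --k 18 -o counts.tsv
kcsf build --counts counts.tsv --scheme amb --minimizers 12,14 --seed 7 -o index.bin
kcsf query --index index.bin --kmers probes.txt
kcsf stats --counts counts.tsv --index index.bin
kcsf suggest --genome-size 1000000 --k 18
```

Count tables use the two-column dump format `<KMER>\t<COUNT>` of common k-mer
counters; indexes are a checksummed binary container that round-trips every
structure bit-exactly.

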