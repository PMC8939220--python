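# Methods

This note records the models, the numerical choices, and what the test
suite does and does not establish.

## The objects

A count table is a static map `f : K → ℕ` from distinct canonical k-mers
(k ≤ 31, 2-bit packed into uint64; canonical = lexicographic minimum of a
k-mer and its reverse complement) to counts ≥ 1.  Count 0 is reserved: it
marks ambiguous buckets in the AMB cascade, which is sound precisely because
absent k-mers are not stored.  All structures obey the static-function
contract: querying a key outside the build set returns an arbitrary decodable
value, never an error.

Canonical counting is the convention of the major k-mer counters; a
`--no-canonical` flag covers strand-specific inputs.  Windows containing N
are skipped entirely (standard counter behaviour), other IUPAC letters are
rejected.

## CSF construction

Values are coded with a canonical, length-limited prefix code.  Lengths come
from Huffman's algorithm, with the package-merge algorithm as the fallback
when the unconstrained depth would exceed the cap (default 32 bits; the cap
bounds the window width and hence query work).  Both paths give optimal
lengths under their constraint, and the realized maximum length, not the cap,
is what queries align windows to.  Only symbols and lengths are serialized;
codewords and decode tables are reconstructed canonically.

Each key receives three windows of `max codeword length` bits, one in each
third of the chunk's bit array (thirds guarantee the three windows are
distinct), at positions derived from splitmix64 hashes of the key under the
chunk seed.  Codeword bit j of a key constrains the XOR of the three
variables at offset j — a 3-variable GF(2) equation.  The system is solved by

1. peeling: repeatedly remove equations containing a degree-1 variable
   (O(total arity), with the degree/XOR-accumulator bookkeeping), then
2. dense bit-packed Gauss–Jordan elimination on the unpeelable 2-core, then
3. back-substitution of the peeled equations in reverse order.

The expansion factor γ (bit-array size over coded size) defaults to 1.10.
This is below the pure-peeling threshold (≈1.23) and slightly above the
3-XOR satisfiability threshold (≈1/0.917 ≈ 1.09), so a 2-core is expected
and the elimination step is what makes γ = 1.10 workable.  Keys are
partitioned by a top-level hash into chunks of at most 2048 keys *and* at
most ~1500 codeword bits, keeping each elimination at desk scale; the
solver kernel is numba-compiled.  An unsolvable chunk (rare; the failure
probability per chunk is a few percent near the threshold) is rebuilt with a
bumped seed, up to 8 attempts, after which the build aborts advising a larger
γ.  Chunk seeds derive deterministically from (global seed, chunk index,
attempt), so builds are bit-reproducible and independent of input order
(keys are sorted before equation construction).

Space accounting: payload is γ × Σ codeword lengths plus 3 × window-width
slack bits per chunk plus ~9 bytes of chunk metadata; for a single-valued
input the code is 0 bits wide and nothing but the code table is stored.

## Bloom dimensioning

The filter uses the classical sizing m = ⌈n·log₂e·log₂(1/ε)⌉ with
round(ln2·m/n) double-hashed probes.  The BCSF decision follows the cost
model exactly as derived in the package docstrings: ε₀ =
(C_BF/C_CSF)·((1−α)/α)·log₂e, filter used iff ε₀ < 1.  C_BF = 1.44.  C_CSF
is taken from the fitted envelope 0.22H₀² + 0.18H₀ + 1.16 (H₀ < 2), else
1.1H₀ + 0.2, evaluated on the full input table, and the same C_CSF is used
on both sides of the comparison.  That envelope was fitted to a particular
reference implementation; our own realized costs differ slightly (γ·avg
codeword length + overheads), so a `CostModel` can be supplied to drive the
decision from measured numbers instead.  The default keeps the fitted
constants because the decision is insensitive to the difference except very
near the threshold.  α = 1 degenerates to a pure constant structure (no
filter, no CSF).

## Cascades

AMB: per layer, buckets with max−min ≤ δ store their minimum (for δ = 0 the
unique value), others store marker 0; marked k-mers survive to the next
layer; survivors of the last layer go to a k-mer-keyed residual BCSF.  The
choice of the *minimum* as representative follows the decreasing shape of
k-mer spectra (smaller counts are more frequent); it also makes collision
detection a running min/max.

FIL: every layer is defined on all of K; layer i stores per-bucket majorities
of the running residual and subtracts them; a final corrections BCSF stores
what remains.  Queries sum all layers plus the correction.  The multi-layer
variant is implemented as this telescoping construction — it makes queries
well-defined for every key and reduces to the single-layer definition
h(q) = f(q) − g(μ_m(q)) when one layer is used.  Majorities are exact
(two-pass histogram); ties break to the smallest value, deterministic and
consistent with the spectrum argument.  Residuals after subtraction can be
negative, so stored values pass through the zigzag map (0→0, −1→1, 1→2, ...),
which keeps 0 — guaranteed modal by the majority rule — the dominant symbol.

Minimizers use a splitmix64 hash order (lexicographic orders have poor
statistics); the order is total via (hash, m-mer) comparison, and equal
windows tie-break leftmost.  Minimizers are computed on the canonical form of
the k-mer — the same key stored in the table — so bucketing and key space
stay consistent.  Per-layer order seeds derive from the build seed and layer
index.

## Length heuristics

First-layer minimizer lengths follow m₀ > m_s = log₄|G| + 2; candidates are
the integers strictly between m_s and k.  When none exist the approximate
cascade with layers (k−2, k−1) is recommended, or a plain BCSF for
degenerate k.  Because compressed size is empirically unimodal in m, the
optional sequential search builds real structures for increasing m and stops
at the first size increase; it is a measurement, not an analytic predictor.

## Synthetic data

Generators are fully seeded.  `random_genome` emulates the whole-genome
regime (i.i.d. bases plus re-inserted repeat units, so repeat k-mers have
counts ≥ 2); `powerlaw_table` draws counts by inverse CDF from a truncated
power law, the shape of real k-mer spectra; `dominant_table` controls the
dominant fraction α directly for dimensioning experiments.  They reproduce
the *statistical* features the structures exploit — skew, heavy tails,
minimizer-shared counts — but not read errors, coverage biases, or the
composition of real genomes, so passing tests demonstrate correctness and
the expected space behaviour, not figures for any particular organism.
Problem sizes in the test suite (10²–10⁵ keys per table in the sweep, a
2 Mbp genome for the bucketing check) were chosen as the smallest scales at
which the asymptotic effects — the 0.59 threshold behaviour, entropy-bound
breaking, ≥90% first-layer resolution — are clearly visible.

## Degenerate inputs and edge cases

Empty tables are rejected everywhere.  Single-valued tables: H₀ = 0, 0-bit
code, constant structures throughout.  Buckets of size one are never
ambiguous.  AMB with δ ≥ max−min of the whole table resolves everything at
layer 1 with no residual.  Duplicate keys and count 0 are build errors, not
silent corruption; the container format detects truncation and bit flips via
per-section CRC32 before answering queries.

## Known limitations

- k ≤ 31 (one uint64 per k-mer); KMC dumps at k = 32 are rejected.
- Counting is in-memory and single-threaded; it targets bacterial-to-small-
  eukaryote scale, not disk-based human-genome counting.
- No membership structure: querying an absent k-mer silently returns an
  arbitrary value, by design.
- Query latency is optimized for vectorized batches; single-key Python calls
  carry interpreter overhead and are not benchmarked against compiled
  implementations (relative ordering of the schemes — CSF fastest, cascades
  slower per extra layer — still holds by construction).
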