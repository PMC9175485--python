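# Methods

## The coding model

A FASTQ block of reads is buffered as a ragged matrix **Q** (row = read in
file order, column = sequencing cycle) and traversed serpentine-wise:
column 0 top-down, column 1 bottom-up, alternating; a column visits exactly
the rows long enough to possess it, in the prevailing direction.  For
ragged inputs this rule is the minimal extension of the rectangular snake
that a decoder can rebuild from the transmitted length vector alone.  The
path is a bijection onto the cells, so coding along it is lossless by
construction.

Each quality symbol is coded with a byte-oriented 32-bit range coder
(integer arithmetic only, explicit carry propagation, frequency totals
capped at 2^16, no end-of-stream symbol — counts travel in the header).
Its per-step frequencies come from adaptive per-context count tables:
counts start at 1 per symbol, grow by `increment` per observation, and are
halved (floor 1) when a context's total exceeds `rescale_limit`.  With the
defaults (increment 32, limit 8192) a table effectively remembers the last
~128 observations, so the coder tracks local statistics — this forgetting
is what makes coding *order* matter at all.

The conditioning state of a symbol combines

1. the previous quality on the scan path, full resolution;
2. the second-previous quality, coarsened to `value // 5`;
3. the read's quantized mean quality (side stream);
4. the current and previous base of the same read, folded to
   {A, C, G, T, other, start} (current base never "start", 36 pairs).

Every component is a function of symbols strictly earlier on the path plus
side streams decoded first (lengths, row bins, bases), verified by a
decoder-replay test.  The row-mean rule is the fixed piecewise map
(collapse below 30; 2-wide bins to 38; pass-through, rounded, above); the
`context_quantizer` module contains the general machinery that derives such
rules: an O(N²K) dynamic program over contiguous partitions of an ordered
condition set minimizing prior-weighted distortion (KL by default; L1/L2
exposed because the distortion measure is genuinely a free choice).  Bin
representatives are the prior-weighted mixtures of member conditionals,
which is the L-optimal representative under KL for fixed membership.

## Container and parameters

Streams per block: read lengths (zigzag deltas as varint bytes, order-0
adaptive; constant-length blocks store a single value), row-mean bin
indices (order-0), optionally the raw base bytes (order-2 folded-base
context; kept verbatim so unusual letters survive), and the quality
bitstream.  Adaptive tables reset at block boundaries so blocks decode
independently; the default block is 100,000 reads, bounding the matrix
buffer while keeping columns long.  A 64-bit checksum of the concatenated
quality values ((CRC-32 << 32) | Adler-32) closes the file; wrong external
bases or a flipped payload byte surface as a checksum failure because the
contexts diverge.

Whether the row-mean context pays is data-dependent, so the default
(`row_mean="auto"`) encodes block 0 with and without it and keeps the
smaller variant file-wide — a deterministic, cheap approximation of
"enable it when the gain exceeds the side-information cost".

Tunables (all serialized in the header, so decoding is parameter-exact):
`increment` 32 and `rescale_limit` 8192 (fast adaptation; larger limits
approach stationary Laplace estimation and weaken order sensitivity),
`q2_div` 5 (second-previous coarsening; 9 levels on a 0–41 alphabet),
`block_size` 100,000, Phred offset 33.  The quality alphabet is sized from
the data (max observed value, up to 93), so the context space scales with
what actually occurs: ≈ 42 × 9 × 8 × 36 ≈ 10⁵ nominal contexts on
Illumina-like data, of which a few thousand are visited.

## The synthetic generator

`synthetic.generate` emulates the observables the contexts target, each
independently switchable: per-cycle mean descent with growing noise
(`mean_start` 38, `mean_slope` −0.05/cycle, noise sd 2.0 + 0.02/cycle);
AR(1) within-read noise (`ar1_rho` 0.8); cross-read correlation
(`cross_read_rho` 0.95, applied to the read-level AR chain and to the
noise innovations across consecutive reads) emulating the near-coincident
quality curves of file-adjacent reads from neighbouring clusters; per-read
level offsets (`read_level_sd` 2.5); and quality dips of 4 Phred firing
with probability 0.1 where the base changes (imaging residue).  Quality is
the rounded, clipped (0–41) sum of these parts.  Under the defaults the
pooled within-read lag-1 autocorrelation is ≈ 0.81 and the fitted
per-cycle mean slope is negative, matching the intended regime.

Presets: `paper-like` (all structure on), `iid` (all off — a memoryless
control on which scan order is irrelevant), `dips-only` and `row-spread`
(each isolates exactly one mechanism with the others off, for ablations).
Isolation matters: with strong cross-read correlation the previous
vertical symbol already carries the read level, and the row bin mostly
dilutes contexts; with everything else silenced the row-mean context is
worth ~0.3 bits/symbol net of its side stream.  What the generator does
*not* model: flowcell geometry, instrument-specific quality binning,
adapter/quality-trimming artifacts, or base-composition bias — so passing
tests demonstrate the mechanisms, not field-ratio claims on real data.

## Evaluation scales and numerical choices

Direction-of-effect checks run at 20,000 reads × 100 cycles (2·10⁶
symbols), large enough that context-dilution transients are small against
the measured gaps; round-trip fuzzing uses hundreds of small adversarial
files (ragged, empty reads, N bases, extreme values 0/93) across codec
configurations.  Tie-breaks: the DP prefers the earliest boundary; row
means round half-to-even in the pass-through branch; empty reads have mean
0 (bin 30).  Degenerate inputs (empty files, zero-length reads, length-1
reads, single-symbol alphabets) are all legal and tested.

## The coding-order experiment, and a known divergence

`coding_order_experiment` codes one symbol multiset (two quantized
Gaussians) in three arrangements with an adaptive order-0 model.  Sorted
(Z3) is dramatically cheapest — order sensitivity is real and large.  But
for the other two arrangements, theory pins the direction: with pure
count-increment adaptation and no rescaling the code length is
permutation-invariant (identical for Z1 and Z2 exactly), and with
rescaling the concatenation Z1 (two stationary halves) codes at most as
large as the shuffle Z2, whose stationary mixture has entropy
H̄ + I ≥ H̄.  Measured (n = 10⁵, defaults): Z3 ≈ 1.4 KB < Z1 ≈ 38.8 KB <
Z2 ≈ 51.1 KB, stable across seeds.  The published ordering this experiment
is sometimes quoted with — shuffle cheaper than concatenation — cannot be
reproduced by a correct adaptive order-0 coder; the corresponding
acceptance test records that inequality and is expected to fail, by
design rather than by defect.

## Limitations

Pure-Python coding loops reach ~0.5 M symbols/s — fine for experiments,
not a production rate.  No random access within a container; blocks are
sequential.  Identifiers are out of scope (side-file passthrough only).
Phred+64 input is handled via `--phred-offset`, not auto-detected.  The
compressor assumes 4-line FASTQ; wrapped FASTQ is rejected to keep the
byte-exact round-trip guarantee honest.
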