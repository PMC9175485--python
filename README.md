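# acoqs — adaptive-coding-order quality-score compression

Quality scores are the hardest-to-compress half of a FASTQ file: a Phred
value (confidence of a base call, stored as `chr(score + 33)`) is drawn
from a large alphabet (~40+ levels), drifts downward along each read as
sequencing chemistry degrades, and is correlated with its neighbours within
and across reads.  `acoqs` is a **lossless** quality-score compressor for
people who store or move NGS data and for people studying context modeling
of sequencing signals.  Instead of the usual raster scan (read after read),
it buffers the block's read-by-cycle quality matrix **Q** and traverses it
in a serpentine (snake) order — column 0 top-down, column 1 bottom-up, … —
so the adaptive coder always sees vertically adjacent symbols from the same
sequencing cycle, a far more stationary stream.

Each symbol `x` is coded by an adaptive range coder under a compound
context

```
ctx(x) = ( q_prev1, ⌊q_prev2 / 5⌋, bin(mean(row)), (j_i, j_{i-1}) )
```

* `q_prev1`, `q_prev2` — previous one/two quality values on the scan path;
* `bin(mean(row))` — the read's mean quality, quantized by the piecewise
  rule `q<30→30, [30,32)→32, [32,34)→34, [34,36)→36, [36,38)→38, else q`
  and transmitted as a side stream (reads with similar means have similar
  distributions);
* `(j_i, j_{i-1})` — the current and previous base of the same read:
  residual signal from the previous incorporation depresses quality where
  the base changes, so `H(X | j_i, j_{i-1}) ≤ H(X | j_i)`.

Per-context symbol counts adapt online (init 1, +32 per observation,
halving above 8192), which is precisely why coding *order* changes output
size.  The package also ships the offline dynamic program that derives
quantizers like the row-mean rule — minimize
`L = Σ_i d(p(x|m_i), Q(p(x|m_i))) p(m_i)` over contiguous K-bin partitions
of an ordered condition set — a synthetic FASTQ generator realizing each
exploited structure switchably, and the standard metrics
`CR = L_after/L_begin × 100 %` and `BPQ = 8·CR/100`.

## Worked example

```sh
python examples/compress_roundtrip.py
```

```
input: 5000 reads, 500000 quality values
serpentine + compound context: 169526 bytes (CR 33.91%, BPQ 2.71)
raster + order-1 baseline:     192878 bytes (CR 38.58%, BPQ 3.09)
round trip byte-identical: True
```

500,000 quality values (one ASCII byte each) shrink to 169,526 bytes —
CR 33.91 % means the compressed stream is a third of the original, i.e.
2.71 bits per quality value instead of 8.  The same coder restricted to a
raster scan and a single previous-quality context needs 0.38 bits/value
more; the gap is the value of the scan order and the compound context.
`decompress(compress(f))` reproduces every quality byte exactly (enforced
by a 64-bit checksum).  The other examples print the coding-order
experiment (`examples/coding_order.py`) and derive a row-mean quantizer
from data (`examples/quantize_row_means.py`).

## Command line

```sh
aco synth --n-reads 10000 --read-len 100 --seed 1 -o reads.fastq
aco compress reads.fastq -o reads.aco [--no-embed-bases] [--raster]
                                      [--block-size B] [--row-mean auto|on|off]
aco decompress reads.aco [-b reads.fastq] [--ids ids.txt] -o back.fastq
aco verify reads.fastq reads.aco
aco stats reads.fastq reads.aco        # L_begin, L_after, CR %, BPQ
aco quantize counts.tsv -k 5           # DP context quantizer on a count table
```

Bases are embedded by default so a container is self-contained; with
`--no-embed-bases` the original bases must be supplied at decompression
(they feed the base context).  Read identifiers are never stored; use
`aco compress --ids` / `aco decompress --ids` to pass them through a side
file when a byte-identical FASTQ rebuild is wanted.

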