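"""Compound context modeling for quality-score coding.

Each quality symbol is coded under a composite conditioning state built from

* the previous quality symbol on the scan path, at full resolution;
* the second-previous symbol on the path, coarsened to ``value // q2_div``;
* the quantized mean quality of the current read (the "row mean" bin),
  transmitted to the decoder as side information;
* a second-order base context: the base under the current quality value and
  the previous base of the *same* read (sequencing residue from the previous
  incorporation perturbs the current one, so quality dips track base
  changes).

Every component is a function of symbols strictly earlier on the scan path
plus side streams the decoder has already read, so the decoder can rebuild
the exact context of every symbol before decoding it.

Per-context symbol statistics are adaptive frequency counts: initialized to
one per symbol (uniform), incremented on each observation, and halved (with
floor one) when the context total exceeds a rescale limit.  The large
increment-to-initial-count ratio makes fresh contexts adapt within a couple
of observations, which keeps the cost of the enlarged context space small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .range_coder import MAX_TOTAL, RangeDecoder, RangeEncoder

#: Quantized row-mean levels below the pass-through region.
ROW_MEAN_LEVELS = (30, 32, 34, 36, 38)

#: Base codes: A=0, C=1, G=2, T=3, anything else (incl. N)=4, start sentinel=5.
BASE_SENTINEL = 5
N_BASE_CODES = 6

_FOLD = [4] * 256
for _i, _b in enumerate("ACGT"):
    _FOLD[ord(_b)] = _i
    _FOLD[ord(_b.lower())] = _i
#: 256-entry table folding a raw base byte to its 5-letter code.
BASE_FOLD: Tuple[int, ...] = tuple(_FOLD)
_BASE_FOLD_NP = np.array(_FOLD, dtype=np.int64)
del _FOLD, _i, _b


# ---------------------------------------------------------------------------
# Row-mean context
# ---------------------------------------------------------------------------

def compute_row_mean(quals: Sequence[int]) -> float:
    """Arithmetic mean quality of a read; an empty read has mean 0."""
    arr = np.asarray(quals, dtype=np.float64)
    if arr.size == 0:
        return 0.0
    return float(arr.mean())


def quantize_row_mean(q: float) -> int:
    """Piecewise quantization of a row mean into its context bin.

    Means below 30 collapse to 30; 30-38 is covered by four 2-wide bins
    labelled by their upper edge; means of 38 and above pass through,
    rounded to the nearest integer so the side stream stays integral.
    """
    if q < 30:
        return 30
    if q < 32:
        return 32
    if q < 34:
        return 34
    if q < 36:
        return 36
    if q < 38:
        return 38
    return int(round(q))


def row_bin_values(qmax: int) -> List[int]:
    """All bin values the quantizer can emit for data with top quality ``qmax``."""
    vals = set(ROW_MEAN_LEVELS)
    vals.update(range(39, max(int(qmax), 38) + 1))
    return sorted(vals)


def row_bin_index(qmax: int) -> Dict[int, int]:
    """Bin value -> dense index, shared by encoder and decoder."""
    return {v: i for i, v in enumerate(row_bin_values(qmax))}


# ---------------------------------------------------------------------------
# Composite context key (reference implementation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContextKey:
    """Composite conditioning state for one quality symbol.

    ``q_prev1``: previous quality on the scan path (0 at block start).
    ``q_prev2_coarse``: second-previous quality, coarsened (0 at block start).
    ``row_bin``: quantized mean of the *current* cell's read.
    ``base_cur``/``base_prev``: folded base codes of the current cell and the
    previous cycle of the same read (:data:`BASE_SENTINEL` at cycle 0).
    """

    q_prev1: int
    q_prev2_coarse: int
    row_bin: int
    base_cur: int
    base_prev: int


def make_context(pos: int,
                 path,
                 matrix_rows: Sequence[np.ndarray],
                 bases: Sequence[str],
                 row_bins: Sequence[int],
                 q2_div: int = 5) -> ContextKey:
    """Build the composite context of the ``pos``-th cell on ``path``.

    Reference (scalar) construction used for tests and documentation; the
    codec computes the same keys vectorized via
    :func:`quality_context_indices`.  Every component depends only on cells
    strictly earlier on the path plus side information, which is what makes
    the stream decodable.
    """
    n = len(path)
    if pos < 0 or pos >= n:
        raise IndexError(f"path position {pos} out of range [0, {n})")
    rows = path.rows
    cols = path.cols
    r = int(rows[pos])
    c = int(cols[pos])
    if pos >= 1:
        q_prev1 = int(matrix_rows[int(rows[pos - 1])][int(cols[pos - 1])])
    else:
        q_prev1 = 0
    if pos >= 2:
        q_prev2 = int(matrix_rows[int(rows[pos - 2])][int(cols[pos - 2])])
    else:
        q_prev2 = 0
    base_cur = BASE_FOLD[ord(bases[r][c])]
    base_prev = BASE_FOLD[ord(bases[r][c - 1])] if c > 0 else BASE_SENTINEL
    return ContextKey(q_prev1, q_prev2 // q2_div, int(row_bins[r]), base_cur, base_prev)


def quality_context_indices(syms: np.ndarray,
                            static_ctx: np.ndarray,
                            q_stride: int,
                            q2_levels: int,
                            q2_div: int) -> np.ndarray:
    """Vectorized encoder-side context index per scan-path position.

    ``syms`` are the quality symbols in path order; the dynamic part of the
    context is the previous one/two symbols on the path (sentinel 0), the
    static part (row bin and base pair, already scaled) is supplied per
    position.  Index layout: ``(q1 * q2_levels + q2_coarse) * q_stride +
    static_ctx``.
    """
    syms = np.asarray(syms, dtype=np.int64)
    n = syms.shape[0]
    prev1 = np.zeros(n, dtype=np.int64)
    if n > 1:
        prev1[1:] = syms[:-1]
    if q2_levels > 1:
        prev2 = np.zeros(n, dtype=np.int64)
        if n > 2:
            prev2[2:] = syms[:-2]
        qpart = prev1 * q2_levels + prev2 // q2_div
    else:
        qpart = prev1
    return qpart * q_stride + np.asarray(static_ctx, dtype=np.int64)


# ---------------------------------------------------------------------------
# Adaptive per-context statistics
# ---------------------------------------------------------------------------

class AdaptiveModel:
    """Lazily-initialized adaptive frequency tables keyed by context.

    Counts start at one per symbol (a fresh context predicts uniformly),
    grow by ``increment`` per observation, and are halved with floor one
    when the context total exceeds ``rescale_limit`` -- an exponential
    forgetting window of roughly ``rescale_limit / (2 * increment)``
    observations, which is what makes coding order matter.
    """

    def __init__(self, alphabet_size: int, increment: int = 32,
                 rescale_limit: int = 8192) -> None:
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        if increment < 1:
            raise ValueError("increment must be >= 1")
        if rescale_limit < alphabet_size:
            raise ValueError("rescale_limit below initial total")
        if rescale_limit + increment > MAX_TOTAL:
            raise ValueError("rescale_limit + increment exceeds coder precision cap")
        self.alphabet_size = alphabet_size
        self.increment = increment
        self.rescale_limit = rescale_limit
        # table layout: alphabet_size counts followed by their total
        self.tables: Dict[object, List[int]] = {}

    def _table(self, key: object) -> List[int]:
        t = self.tables.get(key)
        if t is None:
            a = self.alphabet_size
            t = [1] * (a + 1)
            t[a] = a
            self.tables[key] = t
        return t

    def counts(self, key: object) -> List[int]:
        return self._table(key)[:self.alphabet_size]

    def predict(self, key: object) -> np.ndarray:
        """Probability vector over the alphabet; strictly positive, sums to 1."""
        t = self._table(key)
        a = self.alphabet_size
        return np.asarray(t[:a], dtype=np.float64) / t[a]

    def cumfreqs(self, key: object) -> List[int]:
        """Cumulative counts (length alphabet+1) for the range coder."""
        t = self._table(key)
        out = [0] * (self.alphabet_size + 1)
        acc = 0
        for i in range(self.alphabet_size):
            out[i] = acc
            acc += t[i]
        out[self.alphabet_size] = acc
        return out

    def update(self, key: object, symbol: int) -> None:
        t = self._table(key)
        a = self.alphabet_size
        if not 0 <= symbol < a:
            raise ValueError(f"symbol {symbol} outside alphabet [0, {a})")
        t[symbol] += self.increment
        total = t[a] + self.increment
        if total > self.rescale_limit:
            total = 0
            for j in range(a):
                v = (t[j] + 1) >> 1
                t[j] = v
                total += v
        t[a] = total


# ---------------------------------------------------------------------------
# Hot coding loops (same count arithmetic as AdaptiveModel, inlined)
# ---------------------------------------------------------------------------

def encode_sequence(enc: RangeEncoder,
                    ctxs: Sequence[int],
                    syms: Sequence[int],
                    alphabet: int,
                    increment: int = 32,
                    rescale_limit: int = 8192,
                    tables: Optional[Dict[int, List[int]]] = None) -> Dict[int, List[int]]:
    """Encode ``syms[i]`` under context ``ctxs[i]`` with adaptive counts.

    Count arithmetic is identical to :class:`AdaptiveModel` (verified by
    tests); it is inlined here because this loop dominates compression time.
    """
    if tables is None:
        tables = {}
    get = tables.get
    a = alphabet
    inc = increment
    limit = rescale_limit
    encode = enc.encode
    for ctx, s in zip(ctxs, syms):
        t = get(ctx)
        if t is None:
            t = [1] * (a + 1)
            t[a] = a
            tables[ctx] = t
        total = t[a]
        encode(sum(t[:s]), t[s], total)
        t[s] += inc
        total += inc
        if total > limit:
            total = 0
            for j in range(a):
                v = (t[j] + 1) >> 1
                t[j] = v
                total += v
        t[a] = total
    return tables


def decode_with_contexts(dec: RangeDecoder,
                         ctxs: Sequence[int],
                         alphabet: int,
                         increment: int = 32,
                         rescale_limit: int = 8192,
                         tables: Optional[Dict[int, List[int]]] = None) -> List[int]:
    """Decode one symbol per entry of ``ctxs`` (contexts known in advance)."""
    if tables is None:
        tables = {}
    get = tables.get
    a = alphabet
    inc = increment
    limit = rescale_limit
    out: List[int] = []
    append = out.append
    for ctx in ctxs:
        t = get(ctx)
        if t is None:
            t = [1] * (a + 1)
            t[a] = a
            tables[ctx] = t
        total = t[a]
        f = dec.decode_freq(total)
        cum = 0
        s = 0
        v = t[0]
        while cum + v <= f:
            cum += v
            s += 1
            v = t[s]
        dec.decode_update(cum, v)
        append(s)
        t[s] = v + inc
        total += inc
        if total > limit:
            total = 0
            for j in range(a):
                w = (t[j] + 1) >> 1
                t[j] = w
                total += w
        t[a] = total
    return out


def decode_quality(dec: RangeDecoder,
                   static_ctx: Sequence[int],
                   q_stride: int,
                   q2_levels: int,
                   q2_div: int,
                   alphabet: int,
                   increment: int = 32,
                   rescale_limit: int = 8192) -> List[int]:
    """Decoder mirror of the quality stream.

    The dynamic context components (previous one/two decoded symbols on the
    path) are tracked as the stream is decoded; the static components are
    precomputed from side streams.  Must stay in lockstep with
    :func:`quality_context_indices` + :func:`encode_sequence`.
    """
    tables: Dict[int, List[int]] = {}
    get = tables.get
    a = alphabet
    inc = increment
    limit = rescale_limit
    use2 = q2_levels > 1
    prev1 = 0
    prev2 = 0
    out: List[int] = []
    append = out.append
    for sp in static_ctx:
        if use2:
            ctx = (prev1 * q2_levels + prev2 // q2_div) * q_stride + sp
        else:
            ctx = prev1 * q_stride + sp
        t = get(ctx)
        if t is None:
            t = [1] * (a + 1)
            t[a] = a
            tables[ctx] = t
        total = t[a]
        f = dec.decode_freq(total)
        cum = 0
        s = 0
        v = t[0]
        while cum + v <= f:
            cum += v
            s += 1
            v = t[s]
        dec.decode_update(cum, v)
        append(s)
        t[s] = v + inc
        total += inc
        if total > limit:
            total = 0
            for j in range(a):
                w = (t[j] + 1) >> 1
                t[j] = w
                total += w
        t[a] = total
        prev2 = prev1
        prev1 = s
    return out


def decode_bases(dec: RangeDecoder,
                 lengths: Sequence[int],
                 increment: int = 32,
                 rescale_limit: int = 8192) -> bytes:
    """Decode the embedded base stream (order-2 folded-base context).

    Symbols are raw base bytes; the context is the folded codes of the
    previous two bases of the same read, with the sentinel at read starts.
    """
    tables: Dict[int, List[int]] = {}
    get = tables.get
    a = 256
    inc = increment
    limit = rescale_limit
    fold = BASE_FOLD
    out = bytearray()
    append = out.append
    for ln in lengths:
        p1 = BASE_SENTINEL
        p2 = BASE_SENTINEL
        for _ in range(int(ln)):
            ctx = p1 * N_BASE_CODES + p2
            t = get(ctx)
            if t is None:
                t = [1] * (a + 1)
                t[a] = a
                tables[ctx] = t
            total = t[a]
            f = dec.decode_freq(total)
            cum = 0
            s = 0
            v = t[0]
            while cum + v <= f:
                cum += v
                s += 1
                v = t[s]
            dec.decode_update(cum, v)
            append(s)
            t[s] = v + inc
            total += inc
            if total > limit:
                total = 0
                for j in range(a):
                    w = (t[j] + 1) >> 1
                    t[j] = w
                    total += w
            t[a] = total
            p2 = p1
            p1 = fold[s]
    return bytes(out)


def base_context_indices(folded: np.ndarray, read_starts: np.ndarray) -> np.ndarray:
    """Encoder-side order-2 base contexts for concatenated folded bases.

    ``read_starts`` marks, as a boolean array, the first position of each
    read; the previous-base codes are replaced by the sentinel there (and at
    the second position, for the second-previous code).
    """
    n = folded.shape[0]
    p1 = np.full(n, BASE_SENTINEL, dtype=np.int64)
    p2 = np.full(n, BASE_SENTINEL, dtype=np.int64)
    if n > 1:
        p1[1:] = folded[:-1]
        p1[read_starts] = BASE_SENTINEL
    if n > 2:
        p2[2:] = folded[:-2]
        p2[read_starts] = BASE_SENTINEL
        second = np.zeros(n, dtype=bool)
        second[1:] = read_starts[:-1]
        p2[second] = BASE_SENTINEL
    return p1 * N_BASE_CODES + p2


# ---------------------------------------------------------------------------
# Conditional entropy
# ---------------------------------------------------------------------------

def conditional_entropy(joint_counts) -> float:
    """H(X | M) in bits from a (condition x symbol) count table.

    ``H(X|M) = sum_m p(m) sum_x p(x|m) log2 1/p(x|m)`` with the convention
    ``0 * log(1/0) = 0``.  Raises ``ValueError`` on an all-zero table.
    """
    j = np.asarray(joint_counts, dtype=np.float64)
    if j.ndim != 2:
        raise ValueError("joint_counts must be 2-D (conditions x symbols)")
    if np.any(j < 0):
        raise ValueError("counts must be non-negative")
    total = j.sum()
    if total <= 0:
        raise ValueError("joint count table is all zero")
    row_sums = j.sum(axis=1)
    keep = row_sums > 0
    p_m = row_sums[keep] / total
    p_x_m = j[keep] / row_sums[keep, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p_x_m > 0, p_x_m * np.log2(p_x_m), 0.0)
    return float(-(p_m * terms.sum(axis=1)).sum())
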