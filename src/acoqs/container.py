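"""Compressed container format and the encode/decode drivers.

A container holds everything a decoder needs to reproduce the quality
stream of a FASTQ file exactly:

* a fixed header (format version, Phred offset, model hyperparameters,
  scan/context flags, block geometry) -- sufficient on its own to re-derive
  the scan path and context schema;
* per block of reads: a read-length stream (delta + zigzag + varint bytes,
  order-0 adaptive; constant-length blocks collapse to a single value), a
  row-mean-bin stream (order-0 adaptive, present only when the row-mean
  context is enabled), optionally the base stream (raw base bytes under an
  order-2 folded-base context), and the quality bitstream (compound-context
  adaptive range coding along the configured scan order);
* a trailing 64-bit checksum (CRC-32 and Adler-32 of the raw quality
  values, concatenated) that detects any encoder/decoder divergence.

Read identifiers are not stored: this is a quality-score compressor.  The
CLI offers an identifier passthrough side file for full FASTQ rebuild.
Adaptive statistics are reset at block boundaries, so blocks decode
independently given the header.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .context_model import (
    BASE_SENTINEL,
    N_BASE_CODES,
    _BASE_FOLD_NP,
    base_context_indices,
    compute_row_mean,
    decode_bases,
    decode_quality,
    decode_with_contexts,
    encode_sequence,
    quality_context_indices,
    quantize_row_mean,
    row_bin_index,
    row_bin_values,
)
from .fastq_io import FastqRecord, read_fastq, write_fastq
from .range_coder import MAX_TOTAL, RangeDecoder, RangeEncoder
from .scan_order import raster_path, serpentine_path

MAGIC = b"ACOQ"
VERSION = 1

_FLAG_SERPENTINE = 1
_FLAG_EMBED_BASES = 2
_FLAG_ROW_MEAN = 4
_FLAG_BASE_CONTEXT = 8
_FLAG_PREV2 = 16

_HEADER_FMT = "<4sBBBBBHIIIQQ"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)

_MAX_QUALITY = 93


class ContainerError(ValueError):
    """Invalid, corrupt, or incompatible container data."""


@dataclass
class CodecConfig:
    """Tunable codec parameters; all are recorded in the container header."""

    block_size: int = 100_000
    phred_offset: int = 33
    #: "serpentine" (snake, column-wise) or "raster" (read after read)
    scan: str = "serpentine"
    embed_bases: bool = True
    #: "auto" probes block 0 with and without the row-mean context and keeps
    #: the smaller result file-wide; "on"/"off" force it.
    row_mean: str = "auto"
    base_context: bool = True
    use_prev2: bool = True
    increment: int = 32
    rescale_limit: int = 8192
    q2_div: int = 5

    def validate(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.scan not in ("serpentine", "raster"):
            raise ValueError("scan must be 'serpentine' or 'raster'")
        if self.row_mean not in ("auto", "on", "off"):
            raise ValueError("row_mean must be 'auto', 'on' or 'off'")
        if self.increment < 1:
            raise ValueError("increment must be >= 1")
        if self.rescale_limit < 256:
            raise ValueError("rescale_limit must cover the byte alphabet (>= 256)")
        if self.rescale_limit + self.increment > MAX_TOTAL:
            raise ValueError("rescale_limit + increment exceeds coder precision cap")
        if self.q2_div < 1:
            raise ValueError("q2_div must be >= 1")
        if not 0 <= self.phred_offset <= 93:
            raise ValueError("phred_offset out of range")


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def _zigzag(d: int) -> int:
    return (d << 1) if d >= 0 else ((-d) << 1) - 1

def _unzigzag(z: int) -> int:
    return (z >> 1) if (z & 1) == 0 else -((z + 1) >> 1)


def _varint_symbols(values: Sequence[int]) -> List[int]:
    """Little-endian base-128 bytes (continuation bit 0x80) per value."""
    out: List[int] = []
    for v in values:
        while True:
            b = v & 0x7F
            v >>= 7
            if v:
                out.append(b | 0x80)
            else:
                out.append(b)
                break
    return out


def _checksum(quality_bytes: bytes) -> int:
    return (zlib.crc32(quality_bytes) << 32) | zlib.adler32(quality_bytes)


class _Reader:
    def __init__(self, data: bytes, pos: int = 0) -> None:
        self.data = data
        self.pos = pos

    def take(self, fmt: str):
        size = struct.calcsize(fmt)
        if self.pos + size > len(self.data):
            raise ContainerError("truncated container")
        vals = struct.unpack_from(fmt, self.data, self.pos)
        self.pos += size
        return vals

    def take_bytes(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ContainerError("truncated container")
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out


# ---------------------------------------------------------------------------
# per-block encoding
# ---------------------------------------------------------------------------

def _encode_length_stream(lengths: np.ndarray, cfg: CodecConfig) -> bytes:
    deltas = np.diff(lengths, prepend=0)
    syms = _varint_symbols([_zigzag(int(d)) for d in deltas])
    enc = RangeEncoder()
    encode_sequence(enc, [0] * len(syms), syms, 256, cfg.increment, cfg.rescale_limit)
    return enc.getvalue()


def _decode_length_stream(data: bytes, n_values: int, cfg: CodecConfig) -> np.ndarray:
    """Order-0 adaptive varint decode; symbol count is not known up front."""
    dec = RangeDecoder(data)
    a = 256
    t = [1] * (a + 1)
    t[a] = a
    inc = cfg.increment
    limit = cfg.rescale_limit
    values = []
    acc = 0
    shift = 0
    while len(values) < n_values:
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
        t[s] = v + inc
        total += inc
        if total > limit:
            total = 0
            for j in range(a):
                w = (t[j] + 1) >> 1
                t[j] = w
                total += w
        t[a] = total
        acc |= (s & 0x7F) << shift
        if s & 0x80:
            shift += 7
        else:
            values.append(_unzigzag(acc))
            acc = 0
            shift = 0
    lengths = np.cumsum(np.asarray(values, dtype=np.int64))
    if lengths.size and lengths.min() < 0:
        raise ContainerError("negative read length decoded")
    return lengths


def _fold_block(bases_blk: Sequence[str], lengths: np.ndarray,
                lmax: int) -> np.ndarray:
    """(n_reads, lmax) matrix of folded base codes (padding is arbitrary)."""
    bf = np.zeros((len(bases_blk), lmax), dtype=np.int64)
    for i, b in enumerate(bases_blk):
        if b:
            raw = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
            bf[i, :raw.size] = _BASE_FOLD_NP[raw]
    return bf


def _encode_base_stream(bases_blk: Sequence[str], cfg: CodecConfig) -> bytes:
    chunks = [b.encode("latin-1") for b in bases_blk]
    raw = np.frombuffer(b"".join(chunks), dtype=np.uint8).astype(np.int64)
    if raw.size == 0:
        return b""
    starts = np.zeros(raw.size, dtype=bool)
    pos = 0
    for ch in chunks:
        if ch:
            starts[pos] = True
            pos += len(ch)
    folded = _BASE_FOLD_NP[raw]
    ctxs = base_context_indices(folded, starts)
    enc = RangeEncoder()
    encode_sequence(enc, ctxs.tolist(), raw.tolist(), 256,
                    cfg.increment, cfg.rescale_limit)
    return enc.getvalue()


def _quality_schema(cfg: CodecConfig, qmax: int, row_on: bool,
                    n_bins: int) -> Tuple[int, int, int]:
    """(static stride, base-pair block size, q2 levels) of the context layout."""
    bp_size = N_BASE_CODES * N_BASE_CODES if cfg.base_context else 1
    stride = (n_bins * bp_size) if row_on else bp_size
    q2_levels = (qmax // cfg.q2_div + 1) if cfg.use_prev2 else 1
    return stride, bp_size, q2_levels


def _static_contexts(cfg: CodecConfig, row_on: bool, path,
                     bin_idx: Optional[np.ndarray], bf: Optional[np.ndarray],
                     bp_size: int) -> np.ndarray:
    if cfg.base_context:
        assert bf is not None
        bprev = np.full_like(bf, BASE_SENTINEL)
        if bf.shape[1] > 1:
            bprev[:, 1:] = bf[:, :-1]
        bp = bf[path.rows, path.cols] * N_BASE_CODES + bprev[path.rows, path.cols]
    else:
        bp = np.zeros(len(path), dtype=np.int64)
    if row_on:
        assert bin_idx is not None
        return bin_idx[path.rows] * bp_size + bp
    return bp


def _encode_block(quals_blk: List[np.ndarray], bases_blk: List[str],
                  cfg: CodecConfig, row_on: bool, qmax: int,
                  bin_index: Dict[int, int]) -> Tuple[bytes, Dict[str, int]]:
    n = len(quals_blk)
    lengths = np.asarray([q.size for q in quals_blk], dtype=np.int64)
    lmax = int(lengths.max()) if n else 0
    sizes: Dict[str, int] = {"lengths": 0, "rowbin": 0, "bases": 0, "quality": 0}
    parts: List[bytes] = [struct.pack("<I", n)]

    if n == 0 or bool((lengths == lengths[0]).all()):
        parts.append(struct.pack("<BI", 1, int(lengths[0]) if n else 0))
    else:
        stream = _encode_length_stream(lengths, cfg)
        parts.append(struct.pack("<BQ", 0, len(stream)))
        parts.append(stream)
        sizes["lengths"] = len(stream)

    bin_idx = None
    if row_on:
        bins = [quantize_row_mean(compute_row_mean(q)) for q in quals_blk]
        bin_idx = np.asarray([bin_index[b] for b in bins], dtype=np.int64)
        enc = RangeEncoder()
        encode_sequence(enc, [0] * n, bin_idx.tolist(), len(bin_index),
                        cfg.increment, cfg.rescale_limit)
        stream = enc.getvalue()
        parts.append(struct.pack("<Q", len(stream)))
        parts.append(stream)
        sizes["rowbin"] = len(stream)

    if cfg.embed_bases:
        stream = _encode_base_stream(bases_blk, cfg)
        parts.append(struct.pack("<Q", len(stream)))
        parts.append(stream)
        sizes["bases"] = len(stream)

    n_cells = int(lengths.sum())
    if n_cells:
        path = serpentine_path(lengths) if cfg.scan == "serpentine" else raster_path(lengths)
        q_mat = np.zeros((n, lmax), dtype=np.int64)
        for i, q in enumerate(quals_blk):
            q_mat[i, :q.size] = q
        syms = q_mat[path.rows, path.cols]
        stride, bp_size, q2_levels = _quality_schema(cfg, qmax, row_on, len(bin_index))
        bf = _fold_block(bases_blk, lengths, lmax) if cfg.base_context else None
        static = _static_contexts(cfg, row_on, path, bin_idx, bf, bp_size)
        ctxs = quality_context_indices(syms, static, stride, q2_levels, cfg.q2_div)
        enc = RangeEncoder()
        encode_sequence(enc, ctxs.tolist(), syms.tolist(), qmax + 1,
                        cfg.increment, cfg.rescale_limit)
        stream = enc.getvalue()
    else:
        stream = b""
    parts.append(struct.pack("<Q", len(stream)))
    parts.append(stream)
    sizes["quality"] = len(stream)
    return b"".join(parts), sizes


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def compress(records: Iterable[FastqRecord],
             config: Optional[CodecConfig] = None) -> bytes:
    """Compress the quality stream (and optionally bases) of ``records``.

    Raises ``ValueError`` on base/quality length mismatches or quality
    values outside the representable range.
    """
    cfg = config if config is not None else CodecConfig()
    cfg.validate()
    recs = list(records)
    quals = [np.asarray(r.quals, dtype=np.int64) for r in recs]
    bases = [r.bases for r in recs]
    for i, (q, b) in enumerate(zip(quals, bases)):
        if q.size != len(b):
            raise ValueError(f"record {i}: base/quality length mismatch")
        if q.size and (int(q.min()) < 0 or int(q.max()) > _MAX_QUALITY):
            raise ValueError(f"record {i}: quality outside [0, {_MAX_QUALITY}]")
    n_reads = len(recs)
    n_quals = int(sum(q.size for q in quals))
    qmax = int(max((int(q.max()) for q in quals if q.size), default=0))
    bin_index = row_bin_index(qmax)

    block_slices = [(s, min(s + cfg.block_size, n_reads))
                    for s in range(0, n_reads, cfg.block_size)]

    payloads: List[bytes] = []
    if cfg.row_mean == "on":
        row_on = True
    elif cfg.row_mean == "off" or not block_slices:
        row_on = False
    else:  # auto: probe block 0 both ways, keep the smaller, apply file-wide
        s, e = block_slices[0]
        pay_on, sz_on = _encode_block(quals[s:e], bases[s:e], cfg, True, qmax, bin_index)
        pay_off, sz_off = _encode_block(quals[s:e], bases[s:e], cfg, False, qmax, bin_index)
        cost_on = sz_on["quality"] + sz_on["rowbin"] + 8
        row_on = cost_on < sz_off["quality"]
        payloads.append(pay_on if row_on else pay_off)
        block_slices = block_slices[1:]

    for s, e in block_slices:
        payload, _ = _encode_block(quals[s:e], bases[s:e], cfg, row_on, qmax, bin_index)
        payloads.append(payload)

    flags = 0
    if cfg.scan == "serpentine":
        flags |= _FLAG_SERPENTINE
    if cfg.embed_bases:
        flags |= _FLAG_EMBED_BASES
    if row_on:
        flags |= _FLAG_ROW_MEAN
    if cfg.base_context:
        flags |= _FLAG_BASE_CONTEXT
    if cfg.use_prev2:
        flags |= _FLAG_PREV2

    header = struct.pack(_HEADER_FMT, MAGIC, VERSION, flags, cfg.phred_offset,
                         qmax, cfg.q2_div, cfg.increment, cfg.rescale_limit,
                         cfg.block_size, len(payloads), n_reads, n_quals)
    qbytes = (np.concatenate(quals).astype(np.uint8).tobytes()
              if quals else b"")
    trailer = struct.pack("<Q", _checksum(qbytes))
    return header + b"".join(payloads) + trailer


def _parse_header(rd: _Reader) -> Tuple[CodecConfig, bool, int, int, int, int]:
    (magic, version, flags, phred_offset, qmax, q2_div, increment,
     rescale_limit, block_size, n_blocks, n_reads, n_quals) = rd.take(_HEADER_FMT)
    if magic != MAGIC:
        raise ContainerError("not a quality-stream container (bad magic)")
    if version != VERSION:
        raise ContainerError(f"unsupported container version {version}")
    cfg = CodecConfig(
        block_size=block_size,
        phred_offset=phred_offset,
        scan="serpentine" if flags & _FLAG_SERPENTINE else "raster",
        embed_bases=bool(flags & _FLAG_EMBED_BASES),
        row_mean="on" if flags & _FLAG_ROW_MEAN else "off",
        base_context=bool(flags & _FLAG_BASE_CONTEXT),
        use_prev2=bool(flags & _FLAG_PREV2),
        increment=increment,
        rescale_limit=rescale_limit,
        q2_div=q2_div,
    )
    row_on = bool(flags & _FLAG_ROW_MEAN)
    return cfg, row_on, qmax, n_blocks, n_reads, n_quals


def decompress(data: bytes,
               external_bases: Optional[Sequence[str]] = None
               ) -> Tuple[List[np.ndarray], Optional[List[str]]]:
    """Exact inverse of :func:`compress` on the quality stream.

    Returns ``(quality_vectors, bases)`` where ``bases`` is the embedded
    base strings, the supplied external ones, or ``None``.  Raises
    :class:`ContainerError` on checksum mismatch, truncation, version
    mismatch, or missing bases when the context schema requires them.
    """
    rd = _Reader(data)
    cfg, row_on, qmax, n_blocks, n_reads, n_quals = _parse_header(rd)
    bin_index = row_bin_index(qmax)
    n_bins = len(bin_index)
    stride, bp_size, q2_levels = _quality_schema(cfg, qmax, row_on, n_bins)

    if not cfg.embed_bases and cfg.base_context and external_bases is None:
        raise ContainerError(
            "base stream not embedded but required for decoding; "
            "supply the original bases")

    all_quals: List[np.ndarray] = []
    out_bases: Optional[List[str]] = [] if (cfg.embed_bases or external_bases is not None) else None
    read_cursor = 0

    for _ in range(n_blocks):
        (n_blk,) = rd.take("<I")
        (const_flag,) = rd.take("<B")
        if const_flag:
            (const_len,) = rd.take("<I")
            lengths = np.full(n_blk, const_len, dtype=np.int64)
        else:
            (sz,) = rd.take("<Q")
            lengths = _decode_length_stream(rd.take_bytes(sz), n_blk, cfg)
        lmax = int(lengths.max()) if n_blk else 0

        bin_idx = None
        if row_on:
            (sz,) = rd.take("<Q")
            stream = rd.take_bytes(sz)
            idx = decode_with_contexts(RangeDecoder(stream), [0] * n_blk,
                                       n_bins, cfg.increment, cfg.rescale_limit)
            bin_idx = np.asarray(idx, dtype=np.int64)

        if cfg.embed_bases:
            (sz,) = rd.take("<Q")
            stream = rd.take_bytes(sz)
            if int(lengths.sum()):
                raw = decode_bases(RangeDecoder(stream), lengths.tolist(),
                                   cfg.increment, cfg.rescale_limit)
            else:
                raw = b""
            bases_blk: List[str] = []
            pos = 0
            for ln in lengths.tolist():
                bases_blk.append(raw[pos:pos + ln].decode("latin-1"))
                pos += ln
        elif external_bases is not None:
            bases_blk = [str(b) for b in
                         external_bases[read_cursor:read_cursor + n_blk]]
            if len(bases_blk) != n_blk:
                raise ContainerError("fewer external base strings than reads")
            for i, (b, ln) in enumerate(zip(bases_blk, lengths.tolist())):
                if len(b) != ln:
                    raise ContainerError(
                        f"external bases length mismatch at read {read_cursor + i}")
        else:
            bases_blk = [""] * n_blk

        (sz,) = rd.take("<Q")
        stream = rd.take_bytes(sz)
        n_cells = int(lengths.sum())
        if n_cells:
            path = (serpentine_path(lengths) if cfg.scan == "serpentine"
                    else raster_path(lengths))
            bf = _fold_block(bases_blk, lengths, lmax) if cfg.base_context else None
            static = _static_contexts(cfg, row_on, path, bin_idx, bf, bp_size)
            syms = decode_quality(RangeDecoder(stream), static.tolist(), stride,
                                  q2_levels, cfg.q2_div, qmax + 1,
                                  cfg.increment, cfg.rescale_limit)
            q_mat = np.zeros((n_blk, lmax), dtype=np.uint8)
            q_mat[path.rows, path.cols] = np.asarray(syms, dtype=np.uint8)
            quals_blk = [q_mat[i, :ln].copy() for i, ln in enumerate(lengths.tolist())]
        else:
            quals_blk = [np.empty(0, dtype=np.uint8) for _ in range(n_blk)]

        all_quals.extend(quals_blk)
        if out_bases is not None:
            out_bases.extend(bases_blk)
        read_cursor += n_blk

    (stored_sum,) = rd.take("<Q")
    qbytes = (np.concatenate(all_quals).astype(np.uint8).tobytes()
              if all_quals else b"")
    if _checksum(qbytes) != stored_sum:
        raise ContainerError(
            "checksum mismatch: decoded quality stream does not match the "
            "encoded one (corrupt container or wrong external bases)")
    if len(all_quals) != n_reads or sum(q.size for q in all_quals) != n_quals:
        raise ContainerError("container read/quality counts inconsistent")
    return all_quals, out_bases


def stream_sizes(data: bytes) -> Dict[str, int]:
    """Per-stream byte totals of a container, without decoding payloads.

    Keys: header, lengths, rowbin, bases, quality, checksum, overhead,
    total.  Length-prefix bytes of each stream count toward that stream.
    """
    rd = _Reader(data)
    cfg, row_on, _, n_blocks, _, _ = _parse_header(rd)
    sizes = {"header": _HEADER_SIZE, "lengths": 0, "rowbin": 0,
             "bases": 0, "quality": 0, "checksum": 8, "overhead": 0}
    for _ in range(n_blocks):
        rd.take("<I")
        sizes["overhead"] += 4
        (const_flag,) = rd.take("<B")
        sizes["lengths"] += 1
        if const_flag:
            rd.take("<I")
            sizes["lengths"] += 4
        else:
            (sz,) = rd.take("<Q")
            rd.take_bytes(sz)
            sizes["lengths"] += 8 + sz
        if row_on:
            (sz,) = rd.take("<Q")
            rd.take_bytes(sz)
            sizes["rowbin"] += 8 + sz
        if cfg.embed_bases:
            (sz,) = rd.take("<Q")
            rd.take_bytes(sz)
            sizes["bases"] += 8 + sz
        (sz,) = rd.take("<Q")
        rd.take_bytes(sz)
        sizes["quality"] += 8 + sz
    rd.take("<Q")
    sizes["total"] = len(data)
    return sizes


# ---------------------------------------------------------------------------
# file-level convenience
# ---------------------------------------------------------------------------

def compress_file(fastq_path: Union[str, Path], out_path: Union[str, Path],
                  config: Optional[CodecConfig] = None,
                  ids_path: Optional[Union[str, Path]] = None) -> bytes:
    """Compress a FASTQ file; optionally copy identifiers to a side file."""
    cfg = config if config is not None else CodecConfig()
    records = list(read_fastq(fastq_path, offset=cfg.phred_offset))
    if ids_path is not None:
        Path(ids_path).write_text(
            "".join(r.identifier + "\n" for r in records), encoding="latin-1")
    blob = compress(records, cfg)
    Path(out_path).write_bytes(blob)
    return blob


def decompress_file(container_path: Union[str, Path],
                    out_path: Union[str, Path],
                    bases_path: Optional[Union[str, Path]] = None,
                    ids_path: Optional[Union[str, Path]] = None) -> int:
    """Rebuild a FASTQ file from a container.

    Bases come from the container if embedded, else from ``bases_path`` (a
    FASTQ file with the original reads); with neither, bases are written as
    runs of ``N``.  Identifiers come from ``ids_path`` (one per line) if
    given, else are synthesized as ``read_<i>``.
    """
    data = Path(container_path).read_bytes()
    external = None
    if bases_path is not None:
        external = [r.bases for r in read_fastq(bases_path)]
    quals, bases = decompress(data, external_bases=external)
    if bases is None:
        bases = ["N" * q.size for q in quals]
    if ids_path is not None:
        ids = Path(ids_path).read_text(encoding="latin-1").splitlines()
        if len(ids) < len(quals):
            raise ContainerError("identifier side file has too few lines")
    else:
        ids = [f"read_{i}" for i in range(len(quals))]
    rd = _Reader(data)
    cfg, *_ = _parse_header(rd)
    records = [FastqRecord(i, b, q) for i, b, q in zip(ids, bases, quals)]
    return write_fastq(records, out_path, offset=cfg.phred_offset)


def verify_file(fastq_path: Union[str, Path],
                container_path: Union[str, Path]) -> bool:
    """True iff the container reproduces the FASTQ's quality stream exactly."""
    data = Path(container_path).read_bytes()
    rd = _Reader(data)
    cfg, *_ = _parse_header(rd)
    records = list(read_fastq(fastq_path, offset=cfg.phred_offset))
    external = None
    if not cfg.embed_bases:
        external = [r.bases for r in records]
    try:
        quals, _ = decompress(data, external_bases=external)
    except ContainerError:
        return False
    if len(quals) != len(records):
        return False
    return all(np.array_equal(q, r.quals) for q, r in zip(quals, records))
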