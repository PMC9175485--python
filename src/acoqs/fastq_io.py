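"""Strict 4-line FASTQ parsing and serialization.

The codec guarantees a byte-exact round trip of the quality stream, so the
reader is deliberately strict: records must be canonical 4-line FASTQ
(identifier, bases, ``+`` separator, quality string) with Phred+33 quality
characters by default.  Multi-line (wrapped) FASTQ is rejected rather than
normalized.  Gzipped input is transparently decompressed.

Bases are kept verbatim as text (any letter outside A/C/G/T -- including N
and lowercase -- is preserved; folding to the 5-letter context alphabet
happens only inside the context model).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Sequence, Union

import numpy as np

#: Printable ASCII range permitted in a quality string.
QUAL_CHAR_MIN = 33
QUAL_CHAR_MAX = 126


class FastqParseError(ValueError):
    """Malformed FASTQ input; the message names the failing record."""


@dataclass
class FastqRecord:
    """One sequencing read: identifier, base string, integer Phred qualities."""

    identifier: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)

    def __len__(self) -> int:
        return int(self.quals.shape[0])

    def validate(self, offset: int = 33) -> None:
        if len(self.bases) != self.quals.shape[0]:
            raise FastqParseError(
                f"record {self.identifier!r}: base/quality length mismatch "
                f"({len(self.bases)} vs {self.quals.shape[0]})")
        if self.quals.size and int(self.quals.max()) > QUAL_CHAR_MAX - offset:
            raise FastqParseError(
                f"record {self.identifier!r}: quality value above "
                f"{QUAL_CHAR_MAX - offset}")


@dataclass
class QualityMatrix:
    """Ragged quality matrix: row r is read r, column c is cycle c."""

    rows: List[np.ndarray] = field(default_factory=list)
    n_reads: int = 0
    max_len: int = 0


def ascii_to_phred(qual_string: str, offset: int = 33) -> np.ndarray:
    """Quality characters -> integer scores (char code minus offset)."""
    raw = np.frombuffer(qual_string.encode("latin-1"), dtype=np.uint8)
    if raw.size and (int(raw.min()) < QUAL_CHAR_MIN or int(raw.max()) > QUAL_CHAR_MAX):
        raise FastqParseError("quality character outside printable ASCII 33-126")
    if offset != QUAL_CHAR_MIN and raw.size and int(raw.min()) < offset:
        raise FastqParseError(f"quality character below Phred offset {offset}")
    return (raw - offset).astype(np.uint8)


def phred_to_ascii(quals: Sequence[int], offset: int = 33) -> str:
    arr = np.asarray(quals, dtype=np.int64)
    if arr.size and (int(arr.min()) < 0 or int(arr.max()) > QUAL_CHAR_MAX - offset):
        raise ValueError(f"quality values outside [0, {QUAL_CHAR_MAX - offset}]")
    return (arr + offset).astype(np.uint8).tobytes().decode("latin-1")


def _open_text(source: Union[str, Path, IO]) -> IO:
    if isinstance(source, (str, Path)):
        fh = open(source, "rb")
        magic = fh.read(2)
        fh.seek(0)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(fh), encoding="latin-1")
        return io.TextIOWrapper(fh, encoding="latin-1")
    return source


def read_fastq(source: Union[str, Path, IO], offset: int = 33) -> Iterator[FastqRecord]:
    """Yield records from canonical 4-line FASTQ, in file order.

    Raises :class:`FastqParseError` naming the (0-based) record index on a
    truncated record, a missing ``+`` separator, a base/quality length
    mismatch, or a quality character outside ASCII 33-126.
    """
    fh = _open_text(source)
    idx = 0
    while True:
        header = fh.readline()
        if header == "":
            return
        lines = [header, fh.readline(), fh.readline(), fh.readline()]
        if any(ln == "" for ln in lines):
            raise FastqParseError(
                f"record {idx}: truncated (line count not a multiple of 4)")
        lines = [ln.rstrip("\n") for ln in lines]
        if not lines[0].startswith("@"):
            raise FastqParseError(f"record {idx}: header does not start with '@'")
        if not lines[2].startswith("+"):
            raise FastqParseError(f"record {idx}: '+' separator line missing")
        bases = lines[1]
        if len(bases) != len(lines[3]):
            raise FastqParseError(
                f"record {idx}: base/quality length mismatch "
                f"({len(bases)} vs {len(lines[3])})")
        try:
            quals = ascii_to_phred(lines[3], offset)
        except FastqParseError as err:
            raise FastqParseError(f"record {idx}: {err}") from None
        yield FastqRecord(lines[0][1:], bases, quals)
        idx += 1


def write_fastq(records: Iterable[FastqRecord],
                sink: Union[str, Path, IO],
                offset: int = 33) -> int:
    """Write canonical 4-line FASTQ; returns the number of bytes written.

    Inverse of :func:`read_fastq` on canonical input (bare ``+`` line), so
    ``write(read(f))`` reproduces ``f`` byte-identically.
    """
    own = isinstance(sink, (str, Path))
    fh: IO = open(sink, "w", encoding="latin-1", newline="") if own else sink
    try:
        n = 0
        for rec in records:
            chunk = f"@{rec.identifier}\n{rec.bases}\n+\n{phred_to_ascii(rec.quals, offset)}\n"
            fh.write(chunk)
            n += len(chunk)
        return n
    finally:
        if own:
            fh.close()


def build_matrix(records: Sequence[FastqRecord]) -> QualityMatrix:
    """Stack record qualities into the ragged read-by-cycle matrix."""
    rows = [np.asarray(r.quals, dtype=np.uint8) for r in records]
    max_len = max((r.shape[0] for r in rows), default=0)
    return QualityMatrix(rows=rows, n_reads=len(rows), max_len=int(max_len))
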