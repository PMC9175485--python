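"""Traversal orders over the read-by-cycle quality matrix.

The quality values of a FASTQ block form a ragged matrix: row ``r`` is read
``r`` in file order, column ``c`` is sequencing cycle ``c``.  The serpentine
(snake) order walks column 0 top-to-bottom, column 1 bottom-to-top, and so
on, so consecutive coded symbols are vertical neighbours sampled in the same
cycle -- a far more stationary sequence for an adaptive coder than the
raster (read-after-read) order, which concatenates non-stationary reads and
jumps from the end of one read to the start of the next.

For ragged inputs a column visits exactly the rows whose read is long enough
to possess that column, preserving the alternating direction per column
index.  The path is a deterministic function of the read-length vector, so a
decoder can rebuild it from the transmitted lengths alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class ScanPath:
    """An ordered visit of every cell of a (possibly ragged) matrix.

    ``rows[i], cols[i]`` is the i-th visited cell.  ``row_lengths`` is the
    shape the path was built for; the path is a bijection onto
    ``{(r, c) : 0 <= c < row_lengths[r]}``.
    """

    rows: np.ndarray
    cols: np.ndarray
    row_lengths: Tuple[int, ...] = field(default=())

    @property
    def cells(self) -> List[Tuple[int, int]]:
        return list(zip(self.rows.tolist(), self.cols.tolist()))

    def __len__(self) -> int:
        return int(self.rows.shape[0])

    def __iter__(self) -> Iterator[Tuple[int, int]]:
        return iter(self.cells)


def _as_lengths(row_lengths: Sequence[int]) -> np.ndarray:
    lens = np.asarray(row_lengths, dtype=np.int64)
    if lens.ndim != 1:
        raise ValueError("row_lengths must be one-dimensional")
    if lens.size and lens.min() < 0:
        raise ValueError("row lengths must be non-negative")
    return lens


def serpentine_path(row_lengths: Sequence[int]) -> ScanPath:
    """Snake traversal: even columns run top-down, odd columns bottom-up.

    A column visits exactly the rows whose length exceeds the column index.
    """
    lens = _as_lengths(row_lengths)
    n_cells = int(lens.sum())
    rows = np.empty(n_cells, dtype=np.int64)
    cols = np.empty(n_cells, dtype=np.int64)
    max_len = int(lens.max()) if lens.size else 0
    pos = 0
    for c in range(max_len):
        present = np.nonzero(lens > c)[0]
        if c & 1:
            present = present[::-1]
        k = present.size
        rows[pos:pos + k] = present
        cols[pos:pos + k] = c
        pos += k
    return ScanPath(rows, cols, tuple(int(v) for v in lens))


def raster_path(row_lengths: Sequence[int]) -> ScanPath:
    """Row-major traversal: each read left to right, read after read."""
    lens = _as_lengths(row_lengths)
    n_cells = int(lens.sum())
    rows = np.repeat(np.arange(lens.size, dtype=np.int64), lens)
    if n_cells:
        cols = np.concatenate([np.arange(int(k), dtype=np.int64) for k in lens if k > 0])
    else:
        cols = np.empty(0, dtype=np.int64)
    return ScanPath(rows, cols, tuple(int(v) for v in lens))


def invert_path(path: ScanPath) -> Dict[Tuple[int, int], int]:
    """Map each cell to its position index; raises on duplicate cells."""
    inv: Dict[Tuple[int, int], int] = {}
    for i, cell in enumerate(zip(path.rows.tolist(), path.cols.tolist())):
        if cell in inv:
            raise ValueError(f"duplicate cell {cell} in scan path")
        inv[cell] = i
    return inv
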