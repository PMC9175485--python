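"""Compression evaluation measures.

Two standard figures summarize quality-stream compression:

* compression rate ``CR = L_after / L_begin * 100`` (percent), where
  ``L_begin`` is the raw quality stream size in bytes (one ASCII byte per
  quality value) and ``L_after`` the compressed size attributable to the
  quality stream;
* bits per quality value ``BPQ = 8 * CR / 100`` (uncompressed ASCII is
  exactly 8 BPQ).

Attribution: the read-length and row-mean-bin side streams exist only to
decode qualities, so they count toward ``L_after`` (as do the header and
checksum); an embedded base stream is a separate payload and is reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import container as _container


def compression_ratio(l_after: float, l_begin: float) -> float:
    """Compressed-to-original size ratio as a percentage."""
    if l_begin <= 0:
        raise ValueError("L_begin must be positive")
    return l_after / l_begin * 100.0


def bits_per_quality(cr_percent: float) -> float:
    """Bits spent per quality value given a compression rate in percent."""
    if cr_percent < 0:
        raise ValueError("CR must be non-negative")
    return 8.0 * cr_percent / 100.0


@dataclass
class CompressionReport:
    """Size accounting for one compress run (bytes; CR percent; BPQ bits)."""

    l_begin: int
    l_after: int
    cr: float
    bpq: float
    base_stream_bytes: int
    total_bytes: int


def report_from_container(data: bytes) -> CompressionReport:
    """Build a :class:`CompressionReport` by parsing a container's streams."""
    sizes = _container.stream_sizes(data)
    rd = _container._Reader(data)
    *_, n_quals = _container._parse_header(rd)
    l_after = sizes["total"] - sizes["bases"]
    cr = compression_ratio(l_after, n_quals)
    return CompressionReport(
        l_begin=n_quals,
        l_after=l_after,
        cr=cr,
        bpq=bits_per_quality(cr),
        base_stream_bytes=sizes["bases"],
        total_bytes=sizes["total"],
    )
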