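"""Byte-oriented 32-bit range coder.

An arithmetic coder over integer frequency counts.  The encoder keeps a
33-bit ``low`` accumulator and a 32-bit ``range`` register; renormalization
emits one byte whenever ``range`` drops below 2**24, with explicit carry
propagation through a cached byte and a run of pending 0xFF bytes.  All
arithmetic is integer-only, so identical inputs produce identical bytes on
every platform.

Frequencies are supplied externally per symbol (typically by an adaptive
context model); totals are capped at 2**16 so the ratio ``range // total``
never loses more than ~2**-8 of precision per coded symbol.  The decoder
does not use an end-of-stream symbol: the caller must know how many symbols
to decode (the container records counts in its header).
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Sequence

TOP = 1 << 24
MASK32 = 0xFFFFFFFF
#: Largest allowed cumulative frequency total for a single coding step.
MAX_TOTAL = 1 << 16
#: Bytes emitted by a flush (includes the leading cache byte).
FLUSH_BYTES = 5


class RangeEncoder:
    """Streaming range encoder writing to an internal byte buffer."""

    __slots__ = ("_low", "_range", "_cache", "_cache_size", "_out", "_flushed")

    def __init__(self) -> None:
        self._low = 0
        self._range = MASK32
        self._cache = 0
        self._cache_size = 1
        self._out = bytearray()
        self._flushed = False

    def _shift_low(self) -> None:
        low = self._low
        if (low & MASK32) < 0xFF000000 or low > MASK32:
            carry = low >> 32
            out = self._out
            out.append((self._cache + carry) & 0xFF)
            if self._cache_size > 1:
                ff = (0xFF + carry) & 0xFF
                out.extend([ff] * (self._cache_size - 1))
            self._cache_size = 0
            self._cache = (low >> 24) & 0xFF
        self._cache_size += 1
        self._low = (low << 8) & MASK32

    def encode(self, cum: int, freq: int, total: int) -> None:
        """Narrow the interval to ``[cum, cum+freq) / total``.

        Raises ``ValueError`` for a zero/negative frequency (the model must
        keep every symbol codable) or a total above :data:`MAX_TOTAL`.
        """
        if freq <= 0:
            raise ValueError("cannot encode a symbol with zero frequency")
        if total > MAX_TOTAL:
            raise ValueError(f"frequency total {total} exceeds {MAX_TOTAL}")
        if self._flushed:
            raise RuntimeError("encoder already flushed")
        r = self._range // total
        self._low += r * cum
        self._range = r * freq
        while self._range < TOP:
            self._range <<= 8
            self._shift_low()

    def flush(self) -> bytes:
        """Emit the remaining register bytes; idempotent (second call -> b'')."""
        if self._flushed:
            return b""
        self._flushed = True
        start = len(self._out)
        for _ in range(FLUSH_BYTES):
            self._shift_low()
        return bytes(self._out[start:])

    def getvalue(self) -> bytes:
        """Complete output stream; flushes first if needed."""
        if not self._flushed:
            self.flush()
        return bytes(self._out)

    def __len__(self) -> int:
        return len(self._out)


class RangeDecoder:
    """Mirror of :class:`RangeEncoder`; consumes exactly the bytes it wrote."""

    __slots__ = ("_data", "_pos", "_range", "_code", "_r")

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 0
        self._range = MASK32
        self._code = 0
        self._r = 1
        for _ in range(FLUSH_BYTES):
            self._code = ((self._code << 8) | self._next_byte()) & MASK32

    def _next_byte(self) -> int:
        p = self._pos
        if p >= len(self._data):
            raise EOFError("range-coded stream exhausted")
        self._pos = p + 1
        return self._data[p]

    def decode_freq(self, total: int) -> int:
        """Return the scaled code point in ``[0, total)`` for symbol lookup."""
        r = self._range // total
        self._r = r
        f = self._code // r
        return total - 1 if f >= total else f

    def decode_update(self, cum: int, freq: int) -> None:
        """Consume the symbol whose interval is ``[cum, cum+freq)``."""
        r = self._r
        self._code -= cum * r
        self._range = r * freq
        while self._range < TOP:
            self._code = ((self._code << 8) | self._next_byte()) & MASK32
            self._range <<= 8

    def tell(self) -> int:
        return self._pos


def encode_symbol(encoder: RangeEncoder, cumfreqs: Sequence[int], symbol: int) -> None:
    """Encode ``symbol`` given a cumulative frequency vector.

    ``cumfreqs`` has length ``alphabet + 1`` with ``cumfreqs[0] == 0`` and
    ``cumfreqs[-1]`` equal to the total count; it must be non-decreasing and
    strictly increasing at ``symbol``.
    """
    lo = int(cumfreqs[symbol])
    hi = int(cumfreqs[symbol + 1])
    encoder.encode(lo, hi - lo, int(cumfreqs[-1]))


def decode_symbol(decoder: RangeDecoder, cumfreqs: Sequence[int]) -> int:
    """Inverse of :func:`encode_symbol` under the same cumulative counts."""
    cf = [int(c) for c in cumfreqs]
    f = decoder.decode_freq(cf[-1])
    s = bisect_right(cf, f) - 1
    decoder.decode_update(cf[s], cf[s + 1] - cf[s])
    return s
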