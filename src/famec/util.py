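"""Unsigned LEB128 varints and little-endian bit streams.

These are the wire primitives for the archive's integer and flag streams.
"""

from __future__ import annotations

from .errors import StreamUnderrunError

__all__ = ["write_varint", "read_varint", "encode_varints", "VarintReader",
           "BitWriter", "BitReader"]


def write_varint(out: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("varints are unsigned")
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return


def encode_varints(values) -> bytes:
    out = bytearray()
    for v in values:
        write_varint(out, v)
    return bytes(out)


def read_varint(data: bytes, pos: int) -> tuple[int, int]:
    """Decode one varint at *pos*; returns (value, new_pos)."""
    value = 0
    shift = 0
    while True:
        if pos >= len(data):
            raise StreamUnderrunError("varint", pos)
        byte = data[pos]
        pos += 1
        value |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return value, pos
        shift += 7


class VarintReader:
    """Sequential varint cursor over a byte stream, with underrun detection."""

    def __init__(self, data: bytes, name: str = "ints"):
        self._data = data
        self._pos = 0
        self.name = name

    def read(self) -> int:
        if self._pos >= len(self._data):
            raise StreamUnderrunError(self.name, self._pos)
        value, self._pos = read_varint(self._data, self._pos)
        return value

    def exhausted(self) -> bool:
        return self._pos >= len(self._data)


class BitWriter:
    """Append single bits; packed little-endian within each byte."""

    def __init__(self):
        self._bytes = bytearray()
        self.n_bits = 0

    def append(self, bit: int) -> None:
        if self.n_bits % 8 == 0:
            self._bytes.append(0)
        if bit:
            self._bytes[-1] |= 1 << (self.n_bits % 8)
        self.n_bits += 1

    def getvalue(self) -> bytes:
        return bytes(self._bytes)


class BitReader:
    """Sequential bit cursor matching :class:`BitWriter`'s packing."""

    def __init__(self, data: bytes, n_bits: int, name: str = "flags"):
        self._data = data
        self._n_bits = n_bits
        self._pos = 0
        self.name = name

    def read(self) -> int:
        if self._pos >= self._n_bits:
            raise StreamUnderrunError(self.name, self._pos)
        bit = (self._data[self._pos >> 3] >> (self._pos & 7)) & 1
        self._pos += 1
        return bit

    def exhausted(self) -> bool:
        return self._pos >= self._n_bits
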