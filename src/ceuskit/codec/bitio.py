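"""LSB-first bit streams as used by DEFLATE.

Data elements (extra bits, block headers) are packed starting from the least
significant bit of each byte; Huffman codes are packed starting from their
most significant code bit, which :meth:`BitWriter.write_code` handles by
reversing the bit order on write.
"""

from __future__ import annotations

from ..errors import CorruptStreamError


class BitWriter:
    def __init__(self):
        self._out = bytearray()
        self._acc = 0
        self._nbits = 0

    def write_bits(self, value: int, nbits: int) -> None:
        """Append ``nbits`` of ``value``, least significant bit first."""
        self._acc |= (value & ((1 << nbits) - 1)) << self._nbits
        self._nbits += nbits
        while self._nbits >= 8:
            self._out.append(self._acc & 0xFF)
            self._acc >>= 8
            self._nbits -= 8

    def write_code(self, code: int, length: int) -> None:
        """Append a Huffman code (MSB of the code emitted first)."""
        rev = 0
        for _ in range(length):
            rev = (rev << 1) | (code & 1)
            code >>= 1
        self.write_bits(rev, length)

    def align_to_byte(self) -> None:
        if self._nbits:
            self._out.append(self._acc & 0xFF)
            self._acc = 0
            self._nbits = 0

    def write_bytes(self, data: bytes) -> None:
        if self._nbits:
            raise RuntimeError("write_bytes requires byte alignment")
        self._out.extend(data)

    @property
    def bit_length(self) -> int:
        return 8 * len(self._out) + self._nbits

    def getvalue(self) -> bytes:
        self.align_to_byte()
        return bytes(self._out)


class BitReader:
    def __init__(self, data: bytes):
        self._data = data
        self._pos = 0        # byte position
        self._acc = 0
        self._nbits = 0

    def read_bits(self, nbits: int) -> int:
        while self._nbits < nbits:
            if self._pos >= len(self._data):
                raise CorruptStreamError(
                    "unexpected end of stream", category="truncated"
                )
            self._acc |= self._data[self._pos] << self._nbits
            self._pos += 1
            self._nbits += 8
        value = self._acc & ((1 << nbits) - 1)
        self._acc >>= nbits
        self._nbits -= nbits
        return value

    def read_bit(self) -> int:
        return self.read_bits(1)

    def align_to_byte(self) -> None:
        self._acc = 0
        self._nbits = 0

    def read_bytes(self, n: int) -> bytes:
        if self._nbits:
            raise RuntimeError("read_bytes requires byte alignment")
        if self._pos + n > len(self._data):
            raise CorruptStreamError(
                "unexpected end of stream in stored block", category="truncated"
            )
        out = self._data[self._pos : self._pos + n]
        self._pos += n
        return out
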