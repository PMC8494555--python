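"""Byte-oriented run-length encoding.

The stream is a sequence of ``(count, value)`` byte pairs with
``1 <= count <= 255``; runs longer than 255 are split.  Worst case
(no repeats) the output is exactly twice the input.
"""

from __future__ import annotations

from ..errors import CorruptStreamError
from .container import CompressedBlock, make_block, verify_block


def rle_encode(data: bytes) -> CompressedBlock:
    data = bytes(data)
    out = bytearray()
    n = len(data)
    i = 0
    while i < n:
        value = data[i]
        j = i + 1
        while j < n and data[j] == value and j - i < 255:
            j += 1
        out.append(j - i)
        out.append(value)
        i = j
    return make_block("RLE", bytes(out), data)


def rle_decode(block: CompressedBlock) -> bytes:
    if block.algorithm != "RLE":
        raise ValueError(f"not an RLE block: {block.algorithm}")
    payload = block.payload
    if len(payload) % 2 != 0:
        raise CorruptStreamError(
            "RLE payload has an odd byte count (truncated pair)",
            category="malformed-pair",
        )
    out = bytearray()
    for i in range(0, len(payload), 2):
        count = payload[i]
        if count == 0:
            raise CorruptStreamError(
                f"zero run count at payload offset {i}", category="malformed-pair"
            )
        out.extend(payload[i + 1 : i + 2] * count)
    return verify_block(block, bytes(out))
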