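"""Compressed-block container with CRC-32 integrity."""

from __future__ import annotations

import binascii
from dataclasses import dataclass

from ..errors import CorruptStreamError

ALGORITHMS = ("RLE", "HUFFMAN", "DEFLATE")


@dataclass(frozen=True)
class CompressedBlock:
    algorithm: str          # RLE | HUFFMAN | DEFLATE
    payload: bytes          # byte-aligned encoded stream
    original_length: int    # bytes of the original data
    checksum: int           # CRC-32 of the original data


def crc32(data: bytes) -> int:
    return binascii.crc32(data) & 0xFFFFFFFF


def make_block(algorithm: str, payload: bytes, original: bytes) -> CompressedBlock:
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return CompressedBlock(
        algorithm=algorithm,
        payload=bytes(payload),
        original_length=len(original),
        checksum=crc32(original),
    )


def verify_block(block: CompressedBlock, decoded: bytes) -> bytes:
    """Check length and CRC of a decoded stream against the container."""
    if len(decoded) != block.original_length:
        raise CorruptStreamError(
            f"decoded {len(decoded)} bytes, container declares "
            f"{block.original_length}",
            category="bad-stored-length",
        )
    if crc32(decoded) != block.checksum:
        raise CorruptStreamError("CRC-32 mismatch", category="crc-mismatch")
    return decoded
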