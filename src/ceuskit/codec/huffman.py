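"""Canonical Huffman coding.

:func:`huffman_build` produces optimal prefix-code lengths by the classic
two-queue/heap construction and converts them to canonical codes (shorter
codes first, ties broken by symbol index), the form DEFLATE transmits.
A single-symbol alphabet is assigned code length 1 so the code remains
decodable bit-by-bit.

The standalone byte codec (:func:`huffman_compress`) stores its code-length
table in the payload (256 length bytes + a bit count), so blocks are
self-contained; :func:`huffman_encode` / :func:`huffman_decode` are the
table-passed primitives underneath.
"""

from __future__ import annotations

import heapq
import struct
from dataclasses import dataclass
from itertools import count

from ..errors import CorruptStreamError, InvalidInputError
from .bitio import BitReader, BitWriter
from .container import CompressedBlock, make_block, verify_block


@dataclass(frozen=True)
class HuffmanTable:
    """Per-symbol code lengths and the canonical codes derived from them."""

    code_lengths: dict[int, int]   # symbol -> bit length (absent = unused)
    codes: dict[int, int]          # symbol -> canonical code value

    @property
    def kraft_sum(self) -> float:
        return sum(2.0 ** -length for length in self.code_lengths.values())


def canonical_codes(code_lengths: dict[int, int]) -> dict[int, int]:
    """Assign canonical codes: by (length, symbol), counting upward."""
    codes: dict[int, int] = {}
    code = 0
    prev_len = 0
    for sym in sorted(code_lengths, key=lambda s: (code_lengths[s], s)):
        length = code_lengths[sym]
        code <<= length - prev_len
        codes[sym] = code
        code += 1
        prev_len = length
    return codes


def optimal_code_lengths(frequencies: dict[int, int]) -> dict[int, int]:
    """Optimal prefix-code bit lengths for positive-frequency symbols."""
    active = {s: f for s, f in frequencies.items() if f > 0}
    if not active:
        raise InvalidInputError("all frequencies are zero")
    if len(active) == 1:
        return {next(iter(active)): 1}
    tiebreak = count()
    heap = [(f, next(tiebreak), {s: 0}) for s, f in sorted(active.items())]
    heapq.heapify(heap)
    while len(heap) > 1:
        f1, _, d1 = heapq.heappop(heap)
        f2, _, d2 = heapq.heappop(heap)
        merged = {s: depth + 1 for s, depth in d1.items()}
        merged.update({s: depth + 1 for s, depth in d2.items()})
        heapq.heappush(heap, (f1 + f2, next(tiebreak), merged))
    return heap[0][2]


def length_limited_code_lengths(
    frequencies: dict[int, int], max_length: int, min_codes: int = 1
) -> dict[int, int]:
    """Optimal lengths, flattened until no code exceeds ``max_length``.

    Flattening halves the frequencies (floored at 1) and rebuilds; in the
    limit all frequencies reach 1 and the tree is balanced, so termination
    is guaranteed for alphabets of at most ``2**max_length`` symbols.
    ``min_codes`` pads the alphabet with unused low-index symbols so the
    resulting code is complete even for degenerate inputs (DEFLATE's
    dynamic literal/length tree must be decodable).
    """
    freqs = {s: f for s, f in frequencies.items() if f > 0}
    if not freqs:
        raise InvalidInputError("all frequencies are zero")
    if len(freqs) < min_codes:
        for sym in range(min_codes):
            if len(freqs) >= min_codes:
                break
            freqs.setdefault(sym, 1)
    lengths = optimal_code_lengths(freqs)
    while max(lengths.values()) > max_length:
        freqs = {s: max(1, f >> 1) for s, f in freqs.items()}
        lengths = optimal_code_lengths(freqs)
    return lengths


def huffman_build(frequencies: dict[int, int]) -> HuffmanTable:
    """Optimal canonical Huffman table for the given symbol counts."""
    lengths = optimal_code_lengths(frequencies)
    return HuffmanTable(code_lengths=lengths, codes=canonical_codes(lengths))


def huffman_encode(data: bytes, table: HuffmanTable) -> CompressedBlock:
    """Bit-pack ``data`` with ``table``; payload is the padded bitstream."""
    writer = BitWriter()
    codes, lengths = table.codes, table.code_lengths
    for sym in data:
        if sym not in codes:
            raise InvalidInputError(f"symbol {sym} has no code in the table")
        writer.write_code(codes[sym], lengths[sym])
    nbits = writer.bit_length
    block = make_block("HUFFMAN", writer.getvalue(), bytes(data))
    # exact bit length travels out of band for the table-passed primitive
    object.__setattr__(block, "_bit_length", nbits)
    return block


def huffman_decode(
    block: CompressedBlock, table: HuffmanTable, n_symbols: int | None = None
) -> bytes:
    """Decode a bit-packed payload with ``table``.

    ``n_symbols`` defaults to the container's ``original_length`` (one byte
    per symbol for the byte codec).
    """
    if n_symbols is None:
        n_symbols = block.original_length
    decoder = CanonicalDecoder(table.code_lengths)
    reader = BitReader(block.payload)
    out = bytearray()
    for _ in range(n_symbols):
        out.append(decoder.decode(reader))
    return verify_block(block, bytes(out))


class CanonicalDecoder:
    """Bit-serial decoder for a canonical code given per-symbol lengths."""

    def __init__(self, code_lengths: dict[int, int], *, allow_incomplete: bool = False):
        if not code_lengths:
            raise CorruptStreamError("empty code", category="incomplete-code")
        max_len = max(code_lengths.values())
        counts = [0] * (max_len + 1)
        for length in code_lengths.values():
            counts[length] += 1
        kraft = sum(counts[bits] << (max_len - bits) for bits in range(1, max_len + 1))
        full = 1 << max_len
        if kraft > full:
            raise CorruptStreamError(
                "over-subscribed code lengths", category="oversubscribed-code"
            )
        if kraft < full and not (allow_incomplete or len(code_lengths) == 1):
            raise CorruptStreamError(
                "incomplete code lengths", category="incomplete-code"
            )
        # first canonical code and symbol offset per length
        self.max_len = max_len
        self.first = [0] * (max_len + 2)
        self.offsets = [0] * (max_len + 2)
        symbols: list[int] = []
        code = 0
        for bits in range(1, max_len + 1):
            self.first[bits] = code
            self.offsets[bits] = len(symbols)
            for sym in sorted(s for s, l in code_lengths.items() if l == bits):
                symbols.append(sym)
            code = (code + counts[bits]) << 1
        self.counts = counts
        self.symbols = symbols

    def decode(self, reader: BitReader) -> int:
        code = 0
        for bits in range(1, self.max_len + 1):
            code = (code << 1) | reader.read_bit()
            index = code - self.first[bits]
            if index < self.counts[bits]:
                return self.symbols[self.offsets[bits] + index]
        raise CorruptStreamError("invalid Huffman code", category="incomplete-code")


_HUF_HEADER = struct.Struct("<Q")  # bit count of the packed stream


def huffman_compress(data: bytes) -> CompressedBlock:
    """Self-contained Huffman byte codec: 256 length bytes + bit count + bits."""
    data = bytes(data)
    if not data:
        return make_block("HUFFMAN", b"", data)
    freqs: dict[int, int] = {}
    for b in data:
        freqs[b] = freqs.get(b, 0) + 1
    # cap lengths at 255 so each fits in one header byte (never binding in practice)
    lengths = length_limited_code_lengths(freqs, 255)
    codes = canonical_codes(lengths)
    writer = BitWriter()
    for sym in data:
        writer.write_code(codes[sym], lengths[sym])
    nbits = writer.bit_length
    header = bytes(lengths.get(sym, 0) for sym in range(256))
    payload = header + _HUF_HEADER.pack(nbits) + writer.getvalue()
    return make_block("HUFFMAN", payload, data)


def huffman_decompress(block: CompressedBlock) -> bytes:
    if block.algorithm != "HUFFMAN":
        raise ValueError(f"not a HUFFMAN block: {block.algorithm}")
    if block.original_length == 0:
        return verify_block(block, b"")
    payload = block.payload
    if len(payload) < 256 + _HUF_HEADER.size:
        raise CorruptStreamError("Huffman payload truncated", category="truncated")
    lengths = {sym: payload[sym] for sym in range(256) if payload[sym] > 0}
    (nbits,) = _HUF_HEADER.unpack_from(payload, 256)
    bits = payload[256 + _HUF_HEADER.size :]
    if 8 * len(bits) < nbits:
        raise CorruptStreamError("Huffman bitstream truncated", category="truncated")
    decoder = CanonicalDecoder(lengths)
    reader = BitReader(bits)
    out = bytearray()
    for _ in range(block.original_length):
        out.append(decoder.decode(reader))
    return verify_block(block, bytes(out))
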