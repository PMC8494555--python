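"""Raw DEFLATE (RFC 1951) encoder and decoder, built from scratch.

The encoder follows the classic two-stage flow: LZ77 tokenisation first
(literals plus length/distance back-references), then canonical Huffman
coding of the literal/length and distance alphabets.  The two code-length
sequences are themselves run-length coded with the 0-18 code-length alphabet
and transmitted under a third Huffman code whose lengths appear in the
standard permuted order.  Streams use dynamic-Huffman blocks with a
stored-block fallback when coding would expand the data, and are decodable
by any conformant inflater.

The decoder supports stored, fixed-Huffman, and dynamic-Huffman blocks and
reports malformed streams with a defect category.
"""

from __future__ import annotations

from ..errors import CorruptStreamError
from .bitio import BitReader, BitWriter
from .container import CompressedBlock, make_block, verify_block
from .huffman import CanonicalDecoder, canonical_codes, length_limited_code_lengths
from .lz77 import lz77_tokenize

# length code 257+k: (base length, extra bits)
LENGTH_BASE = [
    3, 4, 5, 6, 7, 8, 9, 10, 11, 13, 15, 17, 19, 23, 27, 31, 35, 43, 51, 59,
    67, 83, 99, 115, 131, 163, 195, 227, 258,
]
LENGTH_EXTRA = [
    0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3,
    4, 4, 4, 4, 5, 5, 5, 5, 0,
]
DIST_BASE = [
    1, 2, 3, 4, 5, 7, 9, 13, 17, 25, 33, 49, 65, 97, 129, 193, 257, 385,
    513, 769, 1025, 1537, 2049, 3073, 4097, 6145, 8193, 12289, 16385, 24577,
]
DIST_EXTRA = [
    0, 0, 0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8,
    9, 9, 10, 10, 11, 11, 12, 12, 13, 13,
]
# order in which code-length-code lengths are transmitted
CL_ORDER = [16, 17, 18, 0, 8, 7, 9, 6, 10, 5, 11, 4, 12, 3, 13, 2, 14, 1, 15]

END_OF_BLOCK = 256
MAX_CODE_LEN = 15
MAX_CL_LEN = 7
STORED_CHUNK = 65535


def _length_symbol(length: int) -> tuple[int, int, int]:
    """(code, extra bits, extra value) for a match length 3..258."""
    for k in range(len(LENGTH_BASE) - 1, -1, -1):
        if length >= LENGTH_BASE[k]:
            return 257 + k, LENGTH_EXTRA[k], length - LENGTH_BASE[k]
    raise ValueError(f"invalid match length {length}")


def _dist_symbol(dist: int) -> tuple[int, int, int]:
    """(code, extra bits, extra value) for a match distance 1..32768."""
    for k in range(len(DIST_BASE) - 1, -1, -1):
        if dist >= DIST_BASE[k]:
            return k, DIST_EXTRA[k], dist - DIST_BASE[k]
    raise ValueError(f"invalid match distance {dist}")


def _rle_code_lengths(lengths: list[int]) -> list[tuple[int, int, int]]:
    """Run-length code a code-length sequence with the 0-18 alphabet.

    Yields (symbol, extra bits, extra value): 0-15 literal lengths,
    16 = repeat previous 3-6, 17 = 3-10 zeros, 18 = 11-138 zeros.
    """
    out: list[tuple[int, int, int]] = []
    i = 0
    n = len(lengths)
    prev = -1
    while i < n:
        value = lengths[i]
        run = 1
        while i + run < n and lengths[i + run] == value:
            run += 1
        if value == 0:
            remaining = run
            while remaining >= 11:
                chunk = min(remaining, 138)
                out.append((18, 7, chunk - 11))
                remaining -= chunk
            while remaining >= 3:
                chunk = min(remaining, 10)
                out.append((17, 3, chunk - 3))
                remaining -= chunk
            out.extend((0, 0, 0) for _ in range(remaining))
        else:
            remaining = run
            if value != prev:
                out.append((value, 0, 0))
                remaining -= 1
            while remaining >= 3:
                chunk = min(remaining, 6)
                out.append((16, 2, chunk - 3))
                remaining -= chunk
            out.extend((value, 0, 0) for _ in range(remaining))
        prev = value
        i += run
    return out


def _stored_stream(data: bytes) -> bytes:
    writer = BitWriter()
    n = len(data)
    offset = 0
    while True:
        chunk = data[offset : offset + STORED_CHUNK]
        final = 1 if offset + len(chunk) >= n else 0
        writer.write_bits(final, 1)
        writer.write_bits(0, 2)  # BTYPE=00 stored
        writer.align_to_byte()
        writer.write_bytes(len(chunk).to_bytes(2, "little"))
        writer.write_bytes((len(chunk) ^ 0xFFFF).to_bytes(2, "little"))
        writer.write_bytes(bytes(chunk))
        offset += len(chunk)
        if final:
            break
    return writer.getvalue()


def _dynamic_stream(data: bytes) -> bytes:
    tokens = lz77_tokenize(data)
    # symbol streams and frequencies
    lit_freq: dict[int, int] = {END_OF_BLOCK: 1}
    dist_freq: dict[int, int] = {}
    events: list[tuple] = []
    for tok in tokens:
        if tok.tag == "literal":
            sym = tok.literal_value
            lit_freq[sym] = lit_freq.get(sym, 0) + 1
            events.append((sym, 0, 0, None))
        else:
            lsym, lxb, lxv = _length_symbol(tok.match_length)
            dsym, dxb, dxv = _dist_symbol(tok.match_distance)
            lit_freq[lsym] = lit_freq.get(lsym, 0) + 1
            dist_freq[dsym] = dist_freq.get(dsym, 0) + 1
            events.append((lsym, lxb, lxv, (dsym, dxb, dxv)))
    events.append((END_OF_BLOCK, 0, 0, None))

    lit_lengths = length_limited_code_lengths(lit_freq, MAX_CODE_LEN, min_codes=2)
    if dist_freq:
        dist_lengths = length_limited_code_lengths(dist_freq, MAX_CODE_LEN)
    else:
        dist_lengths = {}  # "no distance codes used": one zero-length code

    lit_codes = canonical_codes(lit_lengths)
    dist_codes = canonical_codes(dist_lengths) if dist_lengths else {}

    hlit = max(257, max(lit_lengths) + 1)
    hdist = max(1, (max(dist_lengths) + 1) if dist_lengths else 1)
    seq = [lit_lengths.get(s, 0) for s in range(hlit)]
    seq += [dist_lengths.get(s, 0) for s in range(hdist)]
    cl_events = _rle_code_lengths(seq)
    cl_freq: dict[int, int] = {}
    for sym, _, _ in cl_events:
        cl_freq[sym] = cl_freq.get(sym, 0) + 1
    cl_lengths = length_limited_code_lengths(cl_freq, MAX_CL_LEN, min_codes=2)
    cl_codes = canonical_codes(cl_lengths)
    hclen = max(
        4, max(k + 1 for k, sym in enumerate(CL_ORDER) if cl_lengths.get(sym, 0) > 0)
    )

    writer = BitWriter()
    writer.write_bits(1, 1)  # BFINAL: a single dynamic block
    writer.write_bits(2, 2)  # BTYPE=10 dynamic
    writer.write_bits(hlit - 257, 5)
    writer.write_bits(hdist - 1, 5)
    writer.write_bits(hclen - 4, 4)
    for sym in CL_ORDER[:hclen]:
        writer.write_bits(cl_lengths.get(sym, 0), 3)
    for sym, xbits, xval in cl_events:
        writer.write_code(cl_codes[sym], cl_lengths[sym])
        if xbits:
            writer.write_bits(xval, xbits)
    for lsym, lxb, lxv, dist in events:
        writer.write_code(lit_codes[lsym], lit_lengths[lsym])
        if lxb:
            writer.write_bits(lxv, lxb)
        if dist is not None:
            dsym, dxb, dxv = dist
            writer.write_code(dist_codes[dsym], dist_lengths[dsym])
            if dxb:
                writer.write_bits(dxv, dxb)
    return writer.getvalue()


def deflate_encode(data: bytes) -> CompressedBlock:
    """Encode ``data`` as a raw RFC 1951 stream (dynamic blocks, stored fallback)."""
    data = bytes(data)
    if not data:
        return make_block("DEFLATE", _stored_stream(data), data)
    dynamic = _dynamic_stream(data)
    if len(dynamic) >= len(data) + 5 * (1 + len(data) // STORED_CHUNK):
        stream = _stored_stream(data)
        if len(stream) < len(dynamic):
            return make_block("DEFLATE", stream, data)
    return make_block("DEFLATE", dynamic, data)


FIXED_LIT_LENGTHS = {
    **{s: 8 for s in range(0, 144)},
    **{s: 9 for s in range(144, 256)},
    **{s: 7 for s in range(256, 280)},
    **{s: 8 for s in range(280, 288)},
}
FIXED_DIST_LENGTHS = {s: 5 for s in range(30)}


def inflate_raw(stream: bytes) -> bytes:
    """Decode a raw RFC 1951 stream (stored, fixed, and dynamic blocks)."""
    reader = BitReader(stream)
    out = bytearray()
    while True:
        final = reader.read_bit()
        btype = reader.read_bits(2)
        if btype == 0:
            reader.align_to_byte()
            header = reader.read_bytes(4)
            length = int.from_bytes(header[:2], "little")
            nlen = int.from_bytes(header[2:], "little")
            if length ^ nlen != 0xFFFF:
                raise CorruptStreamError(
                    "stored block LEN/NLEN mismatch", category="bad-stored-length"
                )
            out.extend(reader.read_bytes(length))
        elif btype == 1:
            _inflate_block(
                reader,
                out,
                CanonicalDecoder(FIXED_LIT_LENGTHS, allow_incomplete=True),
                CanonicalDecoder(FIXED_DIST_LENGTHS, allow_incomplete=True),
            )
        elif btype == 2:
            lit_dec, dist_dec = _read_dynamic_tables(reader)
            _inflate_block(reader, out, lit_dec, dist_dec)
        else:
            raise CorruptStreamError(
                f"reserved block type {btype}", category="bad-block-type"
            )
        if final:
            return bytes(out)


def _read_dynamic_tables(reader: BitReader):
    hlit = reader.read_bits(5) + 257
    hdist = reader.read_bits(5) + 1
    hclen = reader.read_bits(4) + 4
    cl_lengths: dict[int, int] = {}
    for k in range(hclen):
        length = reader.read_bits(3)
        if length:
            cl_lengths[CL_ORDER[k]] = length
    cl_dec = CanonicalDecoder(cl_lengths)
    seq: list[int] = []
    while len(seq) < hlit + hdist:
        sym = cl_dec.decode(reader)
        if sym < 16:
            seq.append(sym)
        elif sym == 16:
            if not seq:
                raise CorruptStreamError(
                    "repeat code with no previous length", category="corrupt"
                )
            seq.extend([seq[-1]] * (3 + reader.read_bits(2)))
        elif sym == 17:
            seq.extend([0] * (3 + reader.read_bits(3)))
        else:
            seq.extend([0] * (11 + reader.read_bits(7)))
    if len(seq) != hlit + hdist:
        raise CorruptStreamError(
            "code-length run overflows the declared counts", category="corrupt"
        )
    lit_lengths = {s: l for s, l in enumerate(seq[:hlit]) if l}
    dist_lengths = {s: l for s, l in enumerate(seq[hlit:]) if l}
    if END_OF_BLOCK not in lit_lengths:
        raise CorruptStreamError(
            "missing end-of-block code", category="incomplete-code"
        )
    lit_dec = CanonicalDecoder(lit_lengths)
    dist_dec = CanonicalDecoder(dist_lengths) if dist_lengths else None
    return lit_dec, dist_dec


def _inflate_block(reader, out: bytearray, lit_dec, dist_dec) -> None:
    while True:
        sym = lit_dec.decode(reader)
        if sym < 256:
            out.append(sym)
        elif sym == END_OF_BLOCK:
            return
        else:
            k = sym - 257
            if k >= len(LENGTH_BASE):
                raise CorruptStreamError(
                    f"invalid length code {sym}", category="corrupt"
                )
            length = LENGTH_BASE[k] + (
                reader.read_bits(LENGTH_EXTRA[k]) if LENGTH_EXTRA[k] else 0
            )
            if dist_dec is None:
                raise CorruptStreamError(
                    "match emitted but no distance code declared",
                    category="corrupt",
                )
            dsym = dist_dec.decode(reader)
            if dsym >= len(DIST_BASE):
                raise CorruptStreamError(
                    f"invalid distance code {dsym}", category="corrupt"
                )
            dist = DIST_BASE[dsym] + (
                reader.read_bits(DIST_EXTRA[dsym]) if DIST_EXTRA[dsym] else 0
            )
            start = len(out) - dist
            if start < 0:
                raise CorruptStreamError(
                    "distance points before output start", category="bad-distance"
                )
            for i in range(length):
                out.append(out[start + i])


def inflate_decode(block: CompressedBlock) -> bytes:
    """Decode a DEFLATE container block and verify length + CRC."""
    if block.algorithm != "DEFLATE":
        raise ValueError(f"not a DEFLATE block: {block.algorithm}")
    return verify_block(block, inflate_raw(block.payload))
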