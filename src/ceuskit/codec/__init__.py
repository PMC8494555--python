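"""From-scratch lossless codecs: RLE, canonical Huffman, and DEFLATE.

All three satisfy ``decode(encode(x)) == x`` for every byte sequence; the
DEFLATE implementation emits and consumes raw RFC 1951 streams, so it is
mutually intelligible with any conformant inflater/deflater.
"""

from .container import ALGORITHMS, CompressedBlock, make_block, verify_block
from .rle import rle_decode, rle_encode
from .huffman import (
    HuffmanTable,
    huffman_build,
    huffman_compress,
    huffman_decode,
    huffman_decompress,
    huffman_encode,
)
from .lz77 import LZ77Token, lz77_detokenize, lz77_tokenize
from .deflate import deflate_encode, inflate_decode, inflate_raw

__all__ = [
    "ALGORITHMS",
    "CompressedBlock",
    "make_block",
    "verify_block",
    "rle_encode",
    "rle_decode",
    "HuffmanTable",
    "huffman_build",
    "huffman_encode",
    "huffman_decode",
    "huffman_compress",
    "huffman_decompress",
    "LZ77Token",
    "lz77_tokenize",
    "lz77_detokenize",
    "deflate_encode",
    "inflate_decode",
    "inflate_raw",
    "encode_with",
    "decode_with",
]


def encode_with(algorithm: str, data: bytes) -> CompressedBlock:
    """Encode ``data`` with the named algorithm (RLE | HUFFMAN | DEFLATE)."""
    algorithm = algorithm.upper()
    if algorithm == "RLE":
        return rle_encode(data)
    if algorithm == "HUFFMAN":
        return huffman_compress(data)
    if algorithm == "DEFLATE":
        return deflate_encode(data)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def decode_with(block: CompressedBlock) -> bytes:
    """Decode a block according to its ``algorithm`` tag."""
    if block.algorithm == "RLE":
        return rle_decode(block)
    if block.algorithm == "HUFFMAN":
        return huffman_decompress(block)
    if block.algorithm == "DEFLATE":
        return inflate_decode(block)
    raise ValueError(f"unknown algorithm {block.algorithm!r}")
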