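"""Codec-facing byte serialization of signals.

The compressors operate on bytes.  Samples are serialized as a 16-byte
header followed by the sample bytes in *byte-planar* order: all least
significant bytes first, then the next plane, and so on.  Interleaved
little-endian bytes of a piecewise-constant 16-bit signal alternate between
low and high byte, destroying every run at byte level; the planar layout
keeps a run of identical samples as runs of identical bytes, which is what
run-length and LZ77 coding exploit.

Header layout (16 bytes, little-endian):
``magic "USIG" | version u8 | kind u8 | width_bits u8 | reserved u8 |
sample_count u64``.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError
from .signal import Signal

MAGIC = b"USIG"
VERSION = 1
_HEADER = struct.Struct("<4sBBBBQ")
HEADER_SIZE = _HEADER.size  # 16

KIND_CODES = {"grass": 0, "defect": 1, "other": 2}
KIND_NAMES = {v: k for k, v in KIND_CODES.items()}
_DTYPES = {8: np.int8, 16: np.int16, 32: np.int32}


def pack_header(signal: Signal) -> bytes:
    return _HEADER.pack(
        MAGIC,
        VERSION,
        KIND_CODES[signal.kind],
        signal.sample_width_bits,
        0,
        len(signal.samples),
    )


def unpack_header(data: bytes, offset: int = 0) -> tuple[str, int, int]:
    """Return (kind, width_bits, sample_count); raises FormatError."""
    if len(data) - offset < HEADER_SIZE:
        raise FormatError("truncated header", offset=len(data))
    magic, version, kind_code, width, _, count = _HEADER.unpack_from(data, offset)
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}", offset=offset)
    if version != VERSION:
        raise FormatError(f"unsupported version {version}", offset=offset + 4)
    if kind_code not in KIND_NAMES:
        raise FormatError(f"unknown kind code {kind_code}", offset=offset + 5)
    if width not in _DTYPES:
        raise FormatError(f"unsupported sample width {width}", offset=offset + 6)
    return KIND_NAMES[kind_code], width, count


def signal_to_stream(signal: Signal) -> bytes:
    """Header + byte-planar sample bytes."""
    width = signal.sample_width_bits
    arr = signal.samples.astype(_DTYPES[width])
    planes = arr.view(np.uint8).reshape(-1, width // 8).T  # little-endian planes
    return pack_header(signal) + planes.tobytes()


def stream_to_signal(data: bytes, source_id: str = "") -> Signal:
    kind, width, count = unpack_header(data)
    nbytes = count * (width // 8)
    payload = data[HEADER_SIZE:]
    if len(payload) != nbytes:
        raise FormatError(
            f"payload holds {len(payload)} bytes, header declares {nbytes}",
            offset=HEADER_SIZE,
        )
    planes = np.frombuffer(payload, dtype=np.uint8).reshape(width // 8, -1)
    arr = np.ascontiguousarray(planes.T).view(_DTYPES[width]).ravel()
    return Signal(
        samples=arr.astype(np.int64),
        kind=kind,
        sample_width_bits=width,
        source_id=source_id,
    )
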