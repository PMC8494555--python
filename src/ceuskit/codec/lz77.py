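"""LZ77 sliding-window tokenizer (literal / length-distance matches).

Greedy longest-match search over a 32 KiB window using a 3-byte hash-chain
index.  Matches are 3..258 bytes at distances 1..32768, and copy-back
semantics allow overlapping matches (distance < length), which is what makes
long runs collapse to a single token.
"""

from __future__ import annotations

from dataclasses import dataclass

MIN_MATCH = 3
MAX_MATCH = 258
WINDOW = 32768

#: positions examined per hash chain before giving up (speed/ratio trade-off)
MAX_CHAIN = 64
#: a match at least this long stops the search early
GOOD_MATCH = 96


@dataclass(frozen=True)
class LZ77Token:
    tag: str                      # "literal" | "match"
    literal_value: int = 0        # byte value, literal only
    match_length: int = 0         # 3..258, match only
    match_distance: int = 0       # 1..32768, match only


def _hash3(data: bytes, i: int) -> int:
    return (data[i] << 16) | (data[i + 1] << 8) | data[i + 2]


def lz77_tokenize(
    data: bytes,
    window: int = WINDOW,
    min_match: int = MIN_MATCH,
    max_match: int = MAX_MATCH,
) -> list[LZ77Token]:
    data = bytes(data)
    n = len(data)
    tokens: list[LZ77Token] = []
    head: dict[int, int] = {}
    prev = [0] * n
    i = 0
    while i < n:
        best_len = 0
        best_dist = 0
        if i + min_match <= n:
            h = _hash3(data, i)
            cand = head.get(h, -1)
            chain = 0
            limit = min(max_match, n - i)
            while cand >= 0 and i - cand <= window and chain < MAX_CHAIN:
                length = 0
                while length < limit and data[cand + length] == data[i + length]:
                    length += 1
                if length > best_len:
                    best_len = length
                    best_dist = i - cand
                    if length >= GOOD_MATCH or length == limit:
                        break
                nxt = prev[cand]
                if nxt >= cand:
                    break
                cand = nxt
                chain += 1
        if best_len >= min_match:
            tokens.append(
                LZ77Token(tag="match", match_length=best_len, match_distance=best_dist)
            )
            # index every position covered by the match
            end = i + best_len
            while i < end:
                if i + min_match <= n:
                    h = _hash3(data, i)
                    prev[i] = head.get(h, -1)
                    head[h] = i
                i += 1
        else:
            tokens.append(LZ77Token(tag="literal", literal_value=data[i]))
            if i + min_match <= n:
                h = _hash3(data, i)
                prev[i] = head.get(h, -1)
                head[h] = i
            i += 1
    return tokens


def lz77_detokenize(tokens: list[LZ77Token]) -> bytes:
    """Reconstruct the byte stream (copy-back; overlapping copies allowed)."""
    out = bytearray()
    for tok in tokens:
        if tok.tag == "literal":
            out.append(tok.literal_value)
        else:
            start = len(out) - tok.match_distance
            if start < 0:
                raise ValueError("match distance points before stream start")
            for k in range(tok.match_length):
                out.append(out[start + k])
    return bytes(out)
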