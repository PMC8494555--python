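"""Compress the two ultrasound signal classes with every codec.

Generates one grass wave (low-amplitude clutter with sparse spikes) and one
defect wave (wide-amplitude echo pulses), runs RLE, Huffman and DEFLATE on
each, and prints the compression ratio.  Lower CR is better; values above
100% mean the codec expanded the data (RLE on a defect wave does exactly
that, which is why the platform policy never pairs them).
"""

from ceuskit import DefectWaveSpec, GrassWaveSpec, generate_defect_wave, generate_grass_wave
from ceuskit.codec import decode_with, encode_with
from ceuskit.serialize import signal_to_stream

for signal in (
    generate_grass_wave(GrassWaveSpec(), seed=1),
    generate_defect_wave(DefectWaveSpec(), seed=1),
):
    raw = signal_to_stream(signal)
    print(f"{signal.kind} wave: {len(signal)} samples, {len(raw)} bytes raw")
    for algo in ("RLE", "HUFFMAN", "DEFLATE"):
        block = encode_with(algo, raw)
        assert decode_with(block) == raw  # lossless by construction
        print(f"  {algo:8s} CR = {100 * len(block.payload) / len(raw):6.1f} %")
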