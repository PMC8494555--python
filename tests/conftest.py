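import numpy as np
import pytest

from ceuskit import (
    DefectWaveSpec,
    GrassWaveSpec,
    PerfusionParams,
    generate_defect_wave,
    generate_grass_wave,
    perfusion_curve,
)


@pytest.fixture(scope="session")
def grass_signal():
    return generate_grass_wave(GrassWaveSpec(), seed=1)


@pytest.fixture(scope="session")
def defect_signal():
    return generate_defect_wave(DefectWaveSpec(), seed=1)


@pytest.fixture(scope="session")
def fast_bolus():
    """Early-peaking, high-amplitude bolus (malignant-like group mean)."""
    return PerfusionParams(t0=8.0, alpha=2.0, beta=5.0, A=20.0, baseline=5.0)


@pytest.fixture(scope="session")
def slow_bolus():
    """Late-peaking, low-amplitude bolus (benign-like group mean)."""
    return PerfusionParams(t0=12.0, alpha=3.0, beta=7.0, A=0.12, baseline=5.0)


@pytest.fixture(scope="session")
def fast_curve(fast_bolus):
    return perfusion_curve(fast_bolus)


def random_byte_inputs(rng: np.random.Generator, n_cases: int, max_len: int = 300):
    """Mixed random and structured byte sequences for codec fuzzing."""
    out = []
    for i in range(n_cases):
        n = int(rng.integers(0, max_len + 1))
        style = i % 5
        if style == 0:
            data = rng.integers(0, 256, size=n, dtype=np.uint8).tobytes()
        elif style == 1:
            data = rng.choice(np.frombuffer(b"ab", dtype=np.uint8), size=n).tobytes()
        elif style == 2:
            data = bytes([int(rng.integers(0, 256))]) * n
        elif style == 3:
            pat = rng.integers(0, 256, size=max(1, n // 10 + 1), dtype=np.uint8).tobytes()
            data = (pat * (n // len(pat) + 1))[:n]
        else:
            ramp = (np.arange(n) % 256).astype(np.uint8)
            data = ramp.tobytes()
        out.append(data)
    return out
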