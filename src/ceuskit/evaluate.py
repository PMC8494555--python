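"""Compression evaluation: ratio, fidelity metrics, policy, benchmark.

Metrics
-------
* ``CR`` (percent): compressed bytes over original bytes, times 100; lower is
  better, values above 100 mean expansion.
* ``R2MSE`` (percent): relative root-mean-square error between original and
  restored samples, ``100 * sqrt(sum((X - X')^2) / sum(X^2))``; identically 0
  for a lossless round trip.
* ``r``: Pearson correlation between original and restored samples;
  identically 1 for a lossless round trip whenever the original is
  non-constant.

Platform policy
---------------
On a PC every codec is fast enough, so the best-ratio algorithm (DEFLATE) is
used for both signal classes.  On an embedded platform DEFLATE compression is
too slow for the high-rate, highly-runnable grass-wave stream, so the policy
is the balanced combination: RLE for grass waves, DEFLATE for defect waves.

Speeds are measured and reported for information only; they are hardware
dependent and excluded from every assertion.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codec
from .errors import InvalidInputError, UndefinedMetricError
from .preprocess import difference_transform, inverse_difference, smooth_grass_wave
from .signal import Signal
from .serialize import signal_to_stream, stream_to_signal

PLATFORMS = ("PC", "embedded")


@dataclass(frozen=True)
class PlatformPolicy:
    """Signal-class to algorithm mapping for one deployment platform."""

    platform: str
    mapping: dict = field(default_factory=dict)


def compression_ratio(n_after: int, n_before: int) -> float:
    """CR in percent: 100 * n_after / n_before."""
    if n_before <= 0:
        raise InvalidInputError("n_before must be positive")
    return 100.0 * n_after / n_before


def relative_rmse(original: Signal, restored: Signal) -> float:
    """Relative RMS error in percent over all samples."""
    x = original.samples.astype(float)
    y = restored.samples.astype(float)
    if len(x) != len(y):
        raise InvalidInputError(
            f"length mismatch: {len(x)} vs {len(y)} samples"
        )
    denom = float(np.sum(x * x))
    if denom == 0.0:
        raise UndefinedMetricError("R2MSE undefined for an all-zero original")
    num = float(np.sum((x - y) ** 2))
    return 100.0 * float(np.sqrt(num / denom))


def fidelity_correlation(original: Signal, restored: Signal) -> float:
    """Pearson correlation between original and restored samples."""
    x = original.samples.astype(float)
    y = restored.samples.astype(float)
    if len(x) != len(y):
        raise InvalidInputError("length mismatch")
    if len(x) < 2:
        raise InvalidInputError("correlation needs at least 2 samples")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise UndefinedMetricError("correlation undefined for constant signals")
    return float(np.corrcoef(x, y)[0, 1])


def select_algorithm(platform: str, kind: str) -> str:
    """Deployment policy: which codec compresses which signal class."""
    if platform not in PLATFORMS:
        raise InvalidInputError(f"unknown platform {platform!r}")
    if kind not in ("grass", "defect"):
        raise InvalidInputError(f"unknown signal kind {kind!r}")
    if platform == "PC":
        return "DEFLATE"
    return "RLE" if kind == "grass" else "DEFLATE"


def default_policy(platform: str) -> PlatformPolicy:
    return PlatformPolicy(
        platform=platform,
        mapping={k: select_algorithm(platform, k) for k in ("grass", "defect")},
    )


@dataclass(frozen=True)
class PreprocessConfig:
    """Which preprocessing steps the benchmark applies per signal class.

    Smoothing is lossy; when enabled, the fidelity reference is the smoothed
    signal (the codec is still judged lossless against what it encoded).
    Differencing is exactly invertible and is undone before computing
    fidelity, so its round trip is covered by the same numbers.
    """

    smooth_grass: bool = False
    difference_defect: bool = True
    smooth_threshold: float | None = None  # None -> 4x MAD default


def _prepare(signal: Signal, cfg: PreprocessConfig) -> tuple[Signal, Signal]:
    """Return (reference signal, codec-input signal)."""
    ref = signal
    work = signal
    if cfg.smooth_grass and signal.kind == "grass":
        work = smooth_grass_wave(signal, cfg.smooth_threshold)
        ref = work
    if cfg.difference_defect and signal.kind == "defect":
        work = difference_transform(work)
    return ref, work


def _restore(decoded: bytes, cfg: PreprocessConfig) -> Signal:
    sig = stream_to_signal(decoded)
    if cfg.difference_defect and sig.kind == "defect" and sig.sample_width_bits == 32:
        sig = inverse_difference(sig)
    return sig


def roundtrip(
    signal: Signal, algorithm: str, cfg: PreprocessConfig | None = None
) -> dict:
    """Encode/decode one signal with one codec and measure everything."""
    cfg = cfg or PreprocessConfig()
    ref, work = _prepare(signal, cfg)
    raw = signal_to_stream(work)
    n_before = len(signal_to_stream(ref))
    t0 = time.perf_counter()
    block = codec.encode_with(algorithm, raw)
    t1 = time.perf_counter()
    decoded = codec.decode_with(block)
    t2 = time.perf_counter()
    restored = _restore(decoded, cfg)
    row = {
        "signal_id": signal.source_id or "unnamed",
        "kind": signal.kind,
        "algorithm": algorithm.upper(),
        "CR_pct": compression_ratio(len(block.payload), n_before),
        "R2MSE_pct": relative_rmse(ref, restored),
        "r": fidelity_correlation(ref, restored)
        if np.var(ref.samples.astype(float)) > 0
        else float("nan"),
        "comp_Bps": n_before / max(t1 - t0, 1e-12),
        "decomp_Bps": n_before / max(t2 - t1, 1e-12),
    }
    return row


def benchmark(
    signals: list[Signal],
    algorithms: list[str],
    preprocessing: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """CR / R2MSE / r / speed for every (signal, algorithm) pair."""
    if not signals or not algorithms:
        raise InvalidInputError("benchmark needs at least one signal and algorithm")
    rows = []
    for sig in signals:
        for algo in algorithms:
            try:
                rows.append(roundtrip(sig, algo, preprocessing))
            except Exception as exc:  # re-raise with context, per contract
                raise type(exc)(
                    f"{algo} on signal {sig.source_id or 'unnamed'!r}: {exc}"
                ) from exc
    return pd.DataFrame(
        rows,
        columns=[
            "signal_id", "kind", "algorithm", "CR_pct", "R2MSE_pct",
            "r", "comp_Bps", "decomp_Bps",
        ],
    )
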