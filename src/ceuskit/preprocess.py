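"""Signal preprocessing ahead of lossless compression.

Two class-specific transforms prepare ultrasound signals for coding:

* grass waves are *smoothed*: isolated spikes ("burrs") are replaced by
  linear interpolation between their flanking clean samples, which shortens
  the amplitude alphabet and lowers the empirical entropy;
* defect waves are *differenced*: ``M[0] = A[0]``, ``M[i] = A[i] - A[i-1]``,
  converting amplitude information into amplitude-change information, which
  concentrates the histogram near zero.  Differencing is exactly invertible
  by cumulative summation, so it costs nothing in fidelity.

Smoothing is deliberately lossy (that is its point) and is the only
non-invertible step in the pipeline.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyInputError, ReconstructionError
from .signal import EntropyReport, Signal

#: smoothing looks this many samples ahead for an opposite-direction partner peak
ADJACENT_PEAK_SPAN = 8
#: window (samples, centred) for the running median used in peak detection
MEDIAN_WINDOW = 9


def default_peak_threshold(signal: Signal) -> float:
    """4x the median absolute deviation of the samples (>= 1)."""
    signal.require_nonempty()
    x = signal.samples.astype(float)
    mad = float(np.median(np.abs(x - np.median(x))))
    return max(4.0 * mad, 1.0)


def _window_median(x: np.ndarray, i: int) -> float:
    half = MEDIAN_WINDOW // 2
    lo = max(0, i - half)
    hi = min(len(x), i + half + 1)
    return float(np.median(x[lo:hi]))


def _is_peak(x: np.ndarray, i: int, threshold: float) -> float:
    """Return the signed deviation if ``x[i]`` is a peak, else 0.

    A peak is a local extremum whose absolute deviation from the median of
    the 9-sample centred window exceeds ``threshold``.
    """
    dev = x[i] - _window_median(x, i)
    if abs(dev) <= threshold:
        return 0.0
    left = x[i - 1] if i > 0 else x[i]
    right = x[i + 1] if i < len(x) - 1 else x[i]
    if dev > 0 and x[i] >= left and x[i] >= right:
        return dev
    if dev < 0 and x[i] <= left and x[i] <= right:
        return dev
    return 0.0


def smooth_grass_wave(signal: Signal, peak_threshold: float | None = None) -> Signal:
    """Remove burrs from a grass wave by flank-to-flank interpolation.

    The scan runs left to right ("appear first, process first"): the earliest
    detected peak is repaired first by replacing its samples with linear
    interpolation between the nearest non-peak samples on each side, then
    detection resumes just before the repaired position, so an adjacent
    opposite-direction partner peak that the repair removed is never touched.
    Output length equals input length.
    """
    signal.require_nonempty()
    if peak_threshold is None:
        peak_threshold = default_peak_threshold(signal)
    if peak_threshold <= 0:
        raise ValueError("peak_threshold must be positive")
    x = signal.samples.astype(float).copy()
    n = len(x)
    i = 1
    while i < n - 1:
        if _is_peak(x, i, peak_threshold) == 0.0:
            i += 1
            continue
        # Extend the repaired region over the contiguous run of deviating
        # samples (this is what absorbs an opposite-sign partner within the
        # adjacency span: it vanishes with the first peak's repair).
        start = i
        end = i
        j = i + 1
        while j < n - 1 and j <= start + ADJACENT_PEAK_SPAN:
            if abs(x[j] - _window_median(x, j)) > peak_threshold:
                end = j
                j += 1
            else:
                break
        left = start - 1
        right = min(end + 1, n - 1)
        xl, xr = x[left], x[right]
        span = max(right - left, 1)
        changed = False
        for k in range(start, right):
            new = xl + (xr - xl) * (k - left) / span
            if new != x[k]:
                changed = True
            x[k] = new
        # detection resumes from the repaired position; guarantee progress
        # if the repair was a no-op (flat deviating plateau between flanks)
        i = start if changed else right
    out = np.rint(x).astype(np.int64)
    return signal.with_samples(out)


def difference_transform(signal: Signal) -> Signal:
    """First-difference transform, first sample passed through unchanged.

    The result is declared on a widened 32-bit width, so differences of
    full-scale 16-bit samples never wrap.
    """
    signal.require_nonempty()
    x = signal.samples
    out = np.empty_like(x)
    out[0] = x[0]
    out[1:] = x[1:] - x[:-1]
    return signal.with_samples(out, sample_width_bits=32)


def inverse_difference(signal: Signal, target_width_bits: int = 16) -> Signal:
    """Exact inverse of :func:`difference_transform` via cumulative sums."""
    signal.require_nonempty()
    out = np.cumsum(signal.samples)
    lo = -(1 << (target_width_bits - 1))
    hi = (1 << (target_width_bits - 1)) - 1
    if out.min() < lo or out.max() > hi:
        raise ReconstructionError(
            f"reconstructed samples exceed the declared {target_width_bits}-bit width"
        )
    return signal.with_samples(out, sample_width_bits=target_width_bits)


def information_entropy(signal: Signal) -> EntropyReport:
    """Shannon entropy (bits/sample) of the empirical sample-value distribution.

    Symbols are the distinct sample values, not bytes: the signals under
    study are 16-bit samples and the quantity of interest is how concentrated
    the amplitude histogram is.  Zero-probability terms contribute nothing.
    """
    signal.require_nonempty()
    _, counts = np.unique(signal.samples, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log2(p)))
    return EntropyReport(
        entropy_bits=max(h, 0.0),
        n_symbols=int(len(signal.samples)),
        alphabet_size=int(len(counts)),
    )
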