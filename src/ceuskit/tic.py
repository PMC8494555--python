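"""Time-intensity-curve (TIC) quantification for contrast-enhanced ultrasound.

After a bolus injection of microbubble contrast, the mean image intensity in
a region of interest rises from a pre-contrast baseline to a peak and washes
out again.  This module extracts the standard perfusion indicators from a
sampled curve, nonparametrically (no model is fitted):

==========  =================================================================
baseline    median intensity over the pre-arrival segment (first 10% of
            samples)
TTP         time of the maximum of the 5-point moving-average-smoothed curve
I_max       that maximum
arrival     first time the smoothed curve exceeds baseline + 10% of the peak
            enhancement (linearly interpolated between samples)
RT          rise time, TTP - arrival
mTT         mean transit time: first moment of the baseline-subtracted
            enhancement for t >= arrival
AUC         trapezoidal area of max(I - baseline, 0) over the window
Grad        wash-in gradient: steepest smoothed slope on [arrival, TTP]
K_UP        base-to-peak chord slope, (I_max - baseline) / RT
K_DOWN      absolute half-descent chord slope; the half-descent time is the
            first post-peak crossing of baseline + 50% of peak enhancement.
            Curves that never fall to half-enhancement inside the window get
            a missing-washout flag (K_DOWN reported absent).
==========  =================================================================

The 10% / 50% thresholds and the 5-point smoothing window are conventions
(vendor packages do not publish theirs); they are exposed in
:class:`Conventions` and shared with the closed-form oracle in the
synthetic-data module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import FlatCurveError, InvalidInputError

MIN_CURVE_SAMPLES = 8


@dataclass(frozen=True)
class Conventions:
    """Threshold and smoothing conventions shared by quantifier and oracle."""

    arrival_fraction: float = 0.10   # of peak enhancement
    descent_fraction: float = 0.50   # of peak enhancement
    smooth_window: int = 5           # samples, moving average
    baseline_fraction: float = 0.10  # of samples used for the baseline median
    oracle_refinement: int = 100     # oracle grid refinement over dt


@dataclass(frozen=True)
class TICurve:
    times: np.ndarray        # s, strictly increasing
    intensities: np.ndarray  # a.u., non-negative
    roi_id: str = "roi"
    window: float = 120.0    # s, observation window

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if len(t) != len(y):
            raise InvalidInputError("times and intensities differ in length")
        if len(t) < MIN_CURVE_SAMPLES:
            raise InvalidInputError(
                f"curve needs at least {MIN_CURVE_SAMPLES} samples"
            )
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if t[0] < -1e-9 or t[-1] > self.window + 1e-6:
            raise InvalidInputError("times must lie within [0, window]")
        if np.any(y < 0):
            raise InvalidInputError("intensities must be non-negative")


@dataclass(frozen=True)
class TICParameters:
    """One curve's perfusion indicators; absent values are ``None``."""

    baseline: float
    arrival_time: float | None
    RT: float | None
    TTP: float | None
    mTT: float | None
    I_max: float
    Grad: float | None
    AUC: float
    K_UP: float | None
    K_DOWN: float | None
    missing_washout: bool = False

    def as_dict(self) -> dict:
        return {
            "baseline": self.baseline, "arrival_time": self.arrival_time,
            "RT": self.RT, "TTP": self.TTP, "mTT": self.mTT,
            "I_max": self.I_max, "Grad": self.Grad, "AUC": self.AUC,
            "K_UP": self.K_UP, "K_DOWN": self.K_DOWN,
        }


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge-truncated windows (length preserved)."""
    if window <= 1:
        return y.astype(float)
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], y.astype(float))))
    n = len(y)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def estimate_baseline(curve: TICurve, conv: Conventions | None = None) -> float:
    """Median intensity over the first ``baseline_fraction`` of samples."""
    conv = conv or Conventions()
    n = max(1, int(round(conv.baseline_fraction * len(curve.times))))
    return float(np.median(curve.intensities[:n]))


def detect_peak(curve: TICurve, conv: Conventions | None = None) -> tuple[float, float]:
    """(TTP, I_max) from the smoothed curve; ties resolve to the earliest time."""
    conv = conv or Conventions()
    s = _smooth(curve.intensities, conv.smooth_window)
    k = int(np.argmax(s))  # argmax returns the first maximum
    return float(curve.times[k]), float(s[k])


def arrival_time(
    curve: TICurve,
    baseline: float,
    i_max: float,
    conv: Conventions | None = None,
) -> float:
    """First (interpolated) time the smoothed curve exceeds the 10% threshold."""
    conv = conv or Conventions()
    if i_max <= baseline:
        raise FlatCurveError("curve shows no enhancement above baseline")
    s = _smooth(curve.intensities, conv.smooth_window)
    thr = baseline + conv.arrival_fraction * (i_max - baseline)
    above = np.nonzero(s > thr)[0]
    if len(above) == 0:
        raise FlatCurveError("smoothed curve never exceeds the arrival threshold")
    k = int(above[0])
    if k == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[k - 1], curve.times[k]
    s0, s1 = s[k - 1], s[k]
    return float(t0 + (thr - s0) * (t1 - t0) / (s1 - s0))


def rise_time(
    curve: TICurve,
    baseline: float | None = None,
    conv: Conventions | None = None,
) -> float:
    """RT = TTP - arrival time."""
    conv = conv or Conventions()
    base = estimate_baseline(curve, conv) if baseline is None else baseline
    ttp, i_max = detect_peak(curve, conv)
    return ttp - arrival_time(curve, base, i_max, conv)


def mean_transit_time(
    curve: TICurve,
    baseline: float | None = None,
    conv: Conventions | None = None,
) -> float:
    """First moment of baseline-subtracted enhancement for t >= arrival."""
    conv = conv or Conventions()
    base = estimate_baseline(curve, conv) if baseline is None else baseline
    ttp, i_max = detect_peak(curve, conv)
    arr = arrival_time(curve, base, i_max, conv)
    t = curve.times
    enh = np.clip(curve.intensities - base, 0.0, None)
    post = t >= arr
    denom = float(np.trapezoid(enh[post], t[post]))
    if denom <= 0:
        raise FlatCurveError("no enhancement mass after arrival")
    return float(np.trapezoid((t[post] - arr) * enh[post], t[post]) / denom)


def auc_trapezoid(
    curve: TICurve,
    baseline: float | None = None,
    conv: Conventions | None = None,
) -> float:
    """Trapezoidal integral of max(I - baseline, 0) over the window."""
    conv = conv or Conventions()
    base = estimate_baseline(curve, conv) if baseline is None else baseline
    enh = np.clip(curve.intensities - base, 0.0, None)
    return float(np.trapezoid(enh, curve.times))


def wash_in_gradient(
    curve: TICurve,
    baseline: float | None = None,
    conv: Conventions | None = None,
) -> float:
    """Steepest smoothed slope between arrival and the peak (Grad)."""
    conv = conv or Conventions()
    base = estimate_baseline(curve, conv) if baseline is None else baseline
    ttp, i_max = detect_peak(curve, conv)
    arr = arrival_time(curve, base, i_max, conv)
    s = _smooth(curve.intensities, conv.smooth_window)
    t = curve.times
    slopes = np.diff(s) / np.diff(t)
    mids = 0.5 * (t[:-1] + t[1:])
    sel = (mids >= arr) & (mids <= ttp)
    if not np.any(sel):
        sel = (t[:-1] >= arr - (t[1] - t[0])) & (t[:-1] <= ttp)
    if not np.any(sel):
        raise FlatCurveError("no rising segment between arrival and peak")
    return float(np.max(slopes[sel]))


def slopes_k(
    curve: TICurve,
    baseline: float | None = None,
    conv: Conventions | None = None,
) -> tuple[float, float | None]:
    """(K_UP, K_DOWN); K_DOWN is ``None`` when washout never reaches 50%."""
    conv = conv or Conventions()
    base = estimate_baseline(curve, conv) if baseline is None else baseline
    ttp, i_max = detect_peak(curve, conv)
    arr = arrival_time(curve, base, i_max, conv)
    rt = ttp - arr
    if rt <= 0:
        raise FlatCurveError("peak precedes arrival; curve is degenerate")
    k_up = (i_max - base) / rt
    half = base + conv.descent_fraction * (i_max - base)
    s = _smooth(curve.intensities, conv.smooth_window)
    t = curve.times
    post = np.nonzero(t > ttp)[0]
    k_down = None
    prev_idx = None
    for k in post:
        if s[k] <= half:
            if prev_idx is None:
                t_half = float(t[k])
            else:
                t0, t1 = t[k - 1], t[k]
                s0, s1 = s[k - 1], s[k]
                t_half = float(t0 + (half - s0) * (t1 - t0) / (s1 - s0)) if s1 != s0 else float(t1)
            k_down = abs((half - i_max) / (t_half - ttp))
            break
        prev_idx = k
    return k_up, k_down


def quantify(curve: TICurve, conv: Conventions | None = None) -> TICParameters:
    """All indicators for one curve; flat curves get enhancement fields absent."""
    conv = conv or Conventions()
    base = estimate_baseline(curve, conv)
    ttp, i_max = detect_peak(curve, conv)
    if i_max <= base:
        return TICParameters(
            baseline=base, arrival_time=None, RT=None, TTP=None, mTT=None,
            I_max=i_max, Grad=None, AUC=auc_trapezoid(curve, base, conv),
            K_UP=None, K_DOWN=None,
        )
    try:
        arr = arrival_time(curve, base, i_max, conv)
    except FlatCurveError:
        return TICParameters(
            baseline=base, arrival_time=None, RT=None, TTP=None, mTT=None,
            I_max=i_max, Grad=None, AUC=auc_trapezoid(curve, base, conv),
            K_UP=None, K_DOWN=None,
        )
    rt = ttp - arr
    mtt = mean_transit_time(curve, base, conv)
    auc = auc_trapezoid(curve, base, conv)
    grad = wash_in_gradient(curve, base, conv)
    k_up, k_down = slopes_k(curve, base, conv)
    return TICParameters(
        baseline=base, arrival_time=arr, RT=rt, TTP=ttp, mTT=mtt,
        I_max=i_max, Grad=grad, AUC=auc, K_UP=k_up, K_DOWN=k_down,
        missing_washout=k_down is None,
    )


def quantify_batch(curves: list[TICurve], conv: Conventions | None = None):
    """DataFrame of indicators, one row per curve (absent values as NaN)."""
    import pandas as pd

    rows = []
    for c in curves:
        p = quantify(c, conv)
        row = {"roi_id": c.roi_id}
        row.update({k: (np.nan if v is None else v) for k, v in p.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)
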