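"""1-D sampled ultrasound amplitude signals.

A :class:`Signal` is an ordered sequence of signed integer amplitudes with a
declared sample width.  Signals carry a ``kind`` tag distinguishing the two
signal classes the compression pipeline treats differently:

* ``grass`` -- low-amplitude clutter ("grass wave"): long piecewise-constant
  runs punctuated by sparse spikes ("burrs");
* ``defect`` -- echo signals ("defect wave"): wide-amplitude pulses, so the
  raw amplitude histogram is broad and the entropy high.

Samples are held as int64 internally; ``sample_width_bits`` declares the
representable width (16 for raw acquisitions, 32 after differencing) and is
validated, so widening transforms cannot silently wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyInputError, InvalidInputError

KINDS = ("grass", "defect", "other")


@dataclass
class Signal:
    samples: np.ndarray
    kind: str = "other"
    sample_width_bits: int = 16
    source_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.samples)
        if arr.dtype.kind == "f":
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError("signal samples must be finite")
            arr = np.rint(arr)
        self.samples = arr.astype(np.int64)
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown signal kind {self.kind!r}")
        if self.sample_width_bits not in (8, 16, 32):
            raise InvalidInputError(
                f"unsupported sample width {self.sample_width_bits}"
            )
        self.validate_width()

    def __len__(self) -> int:
        return len(self.samples)

    def validate_width(self) -> None:
        """Check every sample is representable in the declared width."""
        if len(self.samples) == 0:
            return
        lo = -(1 << (self.sample_width_bits - 1))
        hi = (1 << (self.sample_width_bits - 1)) - 1
        mn, mx = int(self.samples.min()), int(self.samples.max())
        if mn < lo or mx > hi:
            raise InvalidInputError(
                f"sample range [{mn}, {mx}] exceeds signed "
                f"{self.sample_width_bits}-bit width"
            )

    def require_nonempty(self) -> None:
        if len(self.samples) == 0:
            raise EmptyInputError("operation requires a non-empty signal")

    def with_samples(self, samples, *, sample_width_bits: int | None = None) -> "Signal":
        width = self.sample_width_bits if sample_width_bits is None else sample_width_bits
        return replace(self, samples=np.asarray(samples), sample_width_bits=width)

    @property
    def nbytes(self) -> int:
        """Payload size of the raw sample stream in bytes."""
        return len(self.samples) * (self.sample_width_bits // 8)


@dataclass(frozen=True)
class EntropyReport:
    """Empirical Shannon entropy of a signal's sample-value distribution."""

    entropy_bits: float
    n_symbols: int
    alphabet_size: int
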