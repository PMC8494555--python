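# Methods

This note documents the models, conventions and numerical choices behind
`ceuskit`, what the synthetic data emulates, and what passing tests do and
do not show about real acquisitions.

## Signal model and preprocessing

Signals are ordered sequences of signed integer amplitudes with a declared
sample width (16 bit raw, 32 bit after differencing) and a class tag.

**Grass-wave smoothing.** A sample is a *peak* when it is a local extremum
whose absolute deviation from the median of a 9-sample centred window
exceeds a threshold (default 4× the signal's median absolute deviation,
caller-overridable; the robust MAD scale makes the default insensitive to
the spikes it is meant to remove).  Peaks are repaired left to right
("appear first, process first"): the contiguous deviating run — which
absorbs an adjacent opposite-direction partner within an 8-sample span — is
replaced by linear interpolation between its flanking non-peak samples, and
scanning resumes at the repaired position, so a partner peak removed by the
repair is never touched twice.  The pass preserves length and is idempotent
on its own output.  Smoothing is deliberately lossy; it is the only
non-invertible step in the pipeline and is therefore applied *before*
encoding, with fidelity judged against the smoothed signal.

**Defect-wave differencing.** `M[0] = A[0]`, `M[i] = A[i] − A[i−1]`,
declared on a widened 32-bit width so full-scale 16-bit differences never
wrap; the inverse is an exact cumulative sum with an overflow check.
Keeping the transform exactly invertible (rather than wrapping modulo 2¹⁶)
is what lets the end-to-end fidelity metrics (R²MSE, r) cover the
preprocessing round trip as well as the codec.

**Entropy.** Shannon entropy over the empirical distribution of distinct
*sample values*, not bytes: the signals are 16-bit samples, and the
quantity of interest is the concentration of the amplitude histogram that
coding exploits.  Zero-probability terms contribute nothing; the value is
bounded by log₂(alphabet size).

## Codecs

All three codecs operate on bytes and share a container (algorithm tag,
payload, original length, CRC-32 with the standard reflected polynomial).

* **RLE**: `(count, value)` pairs, counts 1–255, longer runs split.  Worst
  case exactly 2× expansion (alternating bytes).
* **Huffman**: optimal code lengths by the classic heap construction,
  converted to canonical codes (shorter first, ties by symbol index).  A
  single-symbol alphabet gets length 1 so the code stays decodable.  The
  standalone codec stores 256 length bytes plus a bit count in the payload.
* **DEFLATE**: greedy LZ77 (window 32768, match 3–258, 3-byte hash chains
  with a 64-entry chain cap and early exit on matches ≥ 96 — a pure
  speed/ratio trade-off that cannot affect correctness) followed by one
  dynamic-Huffman block; literal/length and distance code lengths are
  run-length coded with the 0–18 alphabet and transmitted under a third
  code in the standard permuted order.  Code lengths are limited (15 for
  the data alphabets, 7 for the code-length alphabet) by halving
  frequencies and rebuilding until the bound holds — guaranteed to
  terminate because all-ones frequencies give a balanced tree.  Degenerate
  alphabets are padded to two codes so every transmitted code is complete
  (the one-code distance tree, which the format explicitly allows
  incomplete, excepted).  A stored-block stream (5 bytes overhead per
  65535-byte chunk) is emitted instead whenever dynamic coding would
  expand the data, which bounds worst-case output size.  Conformance to the
  public raw-stream format is a deliberate design decision: it makes the
  encoder testable against an independent inflater (zlib) in both
  directions rather than only against itself.

Byte serialization of signals for the codecs is **byte-planar** (all low
bytes, then the next plane), after a 16-byte header.  Interleaved
little-endian bytes of a piecewise-constant 16-bit signal alternate low/high
bytes, which destroys every run at byte level and makes byte-oriented RLE
expand grass waves 2×; the planar layout keeps sample runs as byte runs.

## Evaluation and policy

CR, R²MSE and Pearson r are computed between the (possibly smoothed)
reference signal and the fully restored signal, so differencing
invertibility is covered by the same numbers.  The printed formula for the
correlation in the source material is typographically garbled; the standard
Pearson definition is the only consistent reading and is what is
implemented.  Compression and decompression speeds are measured and
reported for information only — they are hardware-dependent and excluded
from every assertion.  The platform policy maps (platform, class) to a
codec: PC → DEFLATE for both classes (best ratio, speed ample); embedded →
RLE for grass waves, DEFLATE for defect waves (RLE's speed is needed at the
grass-wave data rate, and RLE would expand defect waves).

## Bolus model and TIC conventions

Curves follow the gamma-variate bolus model
I(t) = baseline + A·(t−t₀)^α·e^{−(t−t₀)/β} for t > t₀, the standard shape
for bolus-injection contrast kinetics, chosen for its closed-form peak:
TTP = t₀ + αβ, peak enhancement A·(αβ)^α·e^{−α}.  Defaults (dt = 0.2 s,
120 s window) give 601 samples per curve, a typical CEUS cine rate.

The quantifier is nonparametric (no model fit) with these conventions, all
config-exposed: baseline = median of the first 10 % of samples (median
rather than mean so early enhancement cannot drag it up); smoothing =
5-point centred moving average with edge-truncated windows; arrival = first
interpolated crossing of baseline + 10 % of peak enhancement; half-descent
= first post-peak crossing of the 50 % level; Grad = steepest smoothed
slope on [arrival, TTP]; K_UP = base-to-peak chord (I_max − baseline)/RT;
K_DOWN = |half-descent chord|.  Grad and K_UP are deliberately distinct
slope notions (instantaneous vs chord) and both are reported.  AUC and mTT
clamp the baseline-subtracted curve at zero so sub-baseline noise cannot
cancel enhancement.  Curves that never fall to half-enhancement inside the
window get a missing-washout flag; K_DOWN is reported absent and such rows
are dropped (with a logged count) from K_DOWN group statistics.

The closed-form/quadrature oracle evaluates the same conventions on the
continuous model: TTP and I_max analytically, crossings by Brent
root-finding, AUC/mTT/Grad on a grid ≥ 100× finer than the sampling step.
On noiseless curves the sampled quantifier agrees with the oracle to well
under 1 % per indicator; the residual is pure discretisation (argmax
quantised to the grid, smoothing bias of order (window·dt)²·curvature).

## Synthetic data: what it does and does not emulate

*Grass waves*: geometric run lengths (mean 20 samples), uniform low
amplitudes (±6 a.u.), sparse uniform spikes (2/1000 samples, magnitude
200–400).  *Defect waves*: 16 Gaussian-windowed echo pulses (envelope
σ = 40 samples) with amplitudes uniform in 2 000–20 000 a.u., carrier
0.01–0.06 cycles/sample — i.e. sampled well above the carrier frequency as
RF acquisition is, so consecutive samples correlate and differencing
concentrates the histogram — plus Gaussian noise (σ = 10).  These match the
qualitative class descriptions (runs and burrs; wide amplitude range, high
entropy); no deposited recordings exist, so amplitude scales and rates are
this package's choices.  Entropy and ratio orderings are asserted on these
fixtures only, not claimed universal.

*Cohorts*: per-subject t₀, β and A are group means times independent
log-normal mean-1 multipliers (CV 0.15); the shape α is held fixed within a
group.  A log-normal shape would make derived indicators exponentially
heavy-tailed (AUC ∝ β^{α+1}·Γ(α+1)·A amplifies a 15 % α-CV into >100 %
indicator CV), which no real cohort shows; varying timing, scale and
amplitude captures realistic between-subject spread while keeping
indicators finite-variance.  Default group means — benign t₀ 12 s, α 3,
β 7 s, A 0.12; malignant t₀ 8 s, α 2, β 5 s, A 20 (baseline 5 a.u., curve
noise σ 2 a.u.) — encode the reported effect directions (malignant: earlier
peak, larger AUC, steeper wash-in, higher I_max) at magnitudes a 52/74
split detects decisively, mirroring the strongly significant findings the
configuration emulates.  Misconfigured directions are logged as warnings,
not errors.  The 20 dB noise condition used in recovery tests is defined as
SNR = 20·log₁₀(RMS(intensity)/σ_noise), the standard RMS signal-to-noise
ratio.

Passing tests on these cohorts shows the *pipeline* recovers configured
effects of this size at these group sizes; it says nothing about patient
populations, scanner physics, motion, or attenuation, none of which are
modelled.

## Statistics

Group comparisons use Welch's t (no variance-homogeneity assumption) with
Welch–Satterthwaite degrees of freedom; proportions use Pearson chi-square
without continuity correction (a corrected variant is available).  No
multiple-testing correction is applied by default, matching the
per-comparison P < 0.05 convention; Holm adjustment is provided but off.
Degenerate paired differences: all-zero → statistic 0, p = 1; constant
non-zero → infinite statistic, p = 0, flagged.  Diagnostic metrics are
exact `Fraction` arithmetic rendered to two decimals.  Power simulation
accepts either a two-group normal shift (validated against the exact
noncentral-t power) or a cohort specification, in which case it tests the
closed-form indicator values (TTP, I_max, AUC) of the drawn parameters —
parameter-level power, before curve noise, chosen so the simulation stays
exact and fast; indicators without closed forms are excluded from this
fast path.

## Problem sizes

Fixtures are 4096-sample signals; codec property checks use 10⁴ fuzzed
inputs per direction; calibration uses 10⁴ null simulations; direction
recovery uses 100 seeded cohort replicates of 126 subjects each.  These
sizes give Monte-Carlo standard errors comfortably below the asserted
tolerances while keeping the whole suite under a minute of compute.

## Known limitations

No 2-D/B-mode simulation; no pharmacokinetic realism beyond the bolus
shape; no motion correction or ROI handling; no streaming codec API or
compression levels; greedy (not lazy) LZ77 matching, so ratios trail a
tuned zlib by a few percent on mixed data; TIC indicators are convention-
dependent where vendor software is silent, and values from different
conventions are not directly comparable.
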