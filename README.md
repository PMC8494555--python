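# ceuskit

Lossless compression of 1-D ultrasound signals and quantitative analysis of
contrast-enhanced ultrasound (CEUS) time–intensity curves, in one tested
Python package.

Ultrasound devices produce two quite different raw-signal classes: *grass
waves* (low-amplitude clutter — long constant runs with sparse spike
"burrs") and *defect waves* (echo pulses with a wide amplitude range and
high sample entropy).  Storing them losslessly at device rates calls for
class-aware compression.  Downstream, CEUS exams of the same equipment are
analysed through time–intensity curves (TICs): the mean intensity of a
region of interest after a microbubble bolus, whose shape indicators
separate benign from malignant lesions.  `ceuskit` implements both halves
for researchers who need a transparent, scriptable alternative to vendor
black boxes.

## What is inside

**Codecs (written from scratch, byte-oriented):**

* run-length encoding — `(count, value)` pairs, counts 1–255;
* canonical Huffman coding — optimal prefix codes from symbol frequencies,
  canonical form, self-contained container;
* DEFLATE — LZ77 tokenisation (32 KiB window, greedy longest match via
  3-byte hash chains) followed by dynamic canonical Huffman coding of the
  literal/length and distance alphabets, with the code-length sequences
  themselves run-length coded; raw streams conform to RFC 1951 and
  cross-decode with zlib in both directions.

Preprocessing: grass-wave spike smoothing (peaks beyond a robust threshold
replaced by flank interpolation; lowers the sample entropy
S = −Σᵢ P(xᵢ) log₂ P(xᵢ)) and defect-wave differencing
Mᵢ = Aᵢ − Aᵢ₋₁ (exactly invertible, concentrates the histogram).
Evaluation: compression ratio CR = 100·N_after/N_before, relative error
R²MSE = 100·√(Σ(X−X′)²/ΣX²), Pearson r between original and restored
samples, and the platform policy (PC → DEFLATE everywhere; embedded → RLE
for grass, DEFLATE for defect, trading ratio for speed).

**TIC quantification:** indicators of the bolus curve — time to peak (TTP),
maximal intensity (I_max), rise time (RT), mean transit time (mTT), area
under the baseline-subtracted curve (AUC), wash-in gradient (Grad),
base-to-peak slope K_UP and absolute half-descent slope K_DOWN — extracted
nonparametrically with documented conventions (10 % arrival threshold, 50 %
descent, 5-point smoothing).

**Synthetic data:** generators for both signal classes, gamma-variate bolus
curves I(t) = baseline + A·(t−t₀)^α·e^{−(t−t₀)/β} (analytic peak at
t₀ + αβ), and benign/malignant cohorts with configurable group effects —
plus a closed-form/quadrature oracle for every indicator.

**Cohort statistics:** Welch and paired t-tests, Pearson chi-square,
pairwise group comparisons with effect directions, diagnostic metrics
(sensitivity, specificity, accuracy, PPV, NPV) in exact rational
arithmetic, and Monte-Carlo power analysis validated against the
noncentral-t closed form.

## Worked example

```bash
python examples/cohort_comparison.py
```

```
parameter    mean1    mean2  statistic  p_value  direction
      TTP     33.1     17.7       27.4 8.87e-38          1
      AUC 2.13e+03 5.14e+03      -9.15 1.71e-15         -1
     Grad     10.9     50.1      -36.9 3.65e-54         -1
    I_max     68.2      282      -20.8 1.38e-39         -1
```

A simulated 52/74 benign/malignant cohort: the malignant group peaks ~15 s
earlier (TTP 17.7 vs 33.1 s), with roughly 2.4× the AUC and a far steeper
wash-in — all Welch p-values ≪ 0.05, matching the configured effect
directions.  `examples/` holds one script per capability (compression,
benchmarking, curve quantification, cohort comparison, power analysis),
and the `ceuskit` CLI exposes the same pipeline from the shell
(`simulate-signal`, `compress`, `decompress`, `benchmark`, `tic`,
`compare`, `power`).

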