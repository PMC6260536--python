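# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecgbeats`, and what the synthetic-data experiments do and do not
demonstrate.

## Signal model and preprocessing

The input is a single-lead sampled ECG `x_r[n]` (arbitrary units, nominally
mV) with beat annotations: R-peak sample indices plus one of 18
single-character beat-type symbols (`N A F L Q V R ! e f J | a E j x / S`;
the isolated QRS-like artifact is stored under its WFDB symbol `|`).

Denoising is expected-value subtraction, `x[n] = x_r[n] − μ` with `μ` the
record mean. This removes the DC component of baseline wander exactly,
preserves every pairwise sample difference, and is idempotent. It does not
remove time-varying drift within a record; a centred moving-average variant
(`window_seconds`) is exposed for that, but constant subtraction is the
default method of this pipeline. No 50/60 Hz notch filter is applied — the
low-frequency band relevant here (≈0–0.3 Hz) is baseline wander, and
power-line interference is outside the pipeline's scope.

## Segmentation

Each beat is exactly 200 samples: `pre = 99` samples before the annotated
R-peak, the peak, and 100 after. At 360 Hz this ≈0.56 s window covers the
P wave (~0.17 s before R) and T wave (~0.28 s after R). The pre/post split
is this package's choice (configurable); only the total of 200 samples is
fixed by the protocol. Beats whose window would cross a record edge are
dropped and counted rather than zero-padded, because padding would inject
artificial discontinuities into the wavelet coefficients.

Records at other sampling rates (e.g. 128 Hz Holter data) are
polyphase-resampled to 360 Hz before segmentation so that "200 samples"
always means the same duration and the subband edges below hold.

## Morphological features

Each beat is decomposed with a 4-level dyadic DWT using PyWavelets' `dmey`
filter (the 62-tap FIR approximation of the Meyer wavelet), symmetric
(half-point) boundary extension. Dyadic subband edges at level L are
`fs/2^(L+1)` and `fs/2^L`: at 360 Hz the level-4 approximation a4 covers
0–11.25 Hz and the level-4 detail d4 covers 11.25–22.5 Hz. Detail levels
1–3 are computed and discarded. For 200-sample beats this yields 69
coefficients per subband (length depends on the filter length and boundary
mode; the actual lengths are carried in the dataset rather than forced to a
round number).

Two numerical facts about `dmey` worth knowing:

- It is only *near*-orthogonal (sum of squared taps 1.0022), so
  analysis→synthesis round trips carry an inherent ~0.6% relative error.
  The test suite asserts reconstruction at 2% and includes an orthogonal
  (db4) control that reconstructs to machine precision, isolating the
  residual as the filter's approximation error.
- Level 4 on 200 samples exceeds the nominal `dwt_max_level`; all
  coefficients experience boundary effects. That is acceptable here because
  the coefficients are used as features, not for reconstruction, and the
  boundary mode is fixed so lengths and effects are identical across beats.

Each subband's (beats × 69) coefficient matrix is reduced to 6 components
by FastICA (negentropy maximisation, logcosh contrast, max 500 iterations,
tolerance 1e-4, fixed seed, unit-variance whitening). "Major" components
are the 6 fitted components ordered by descending |excess kurtosis| of
their training-set source estimates — the most non-Gaussian directions
first, which is ICA's natural ranking; no criterion is prescribed by the
protocol, so this is the package's documented choice. Fitting refuses
rank-deficient coefficient matrices (rank < 6) and warns below 60 training
beats. Concatenating the two projections (a4 first) gives 12 morphological
features.

ICA models are fitted per evaluation fold on training beats only; an
explicit leakage guard raises if any test-flagged beat reaches a fit.

## Dynamic features

With R-peak times in seconds and `RR(i) = R(i+1) − R(i)`:

- `rr_pre(i) = R(i) − R(i−1)`; `rr_post(i) = R(i+1) − R(i)`. Edge beats
  fall back to the nearest defined interval.
- `rr_local(i)`: mean of the up-to-10 intervals nearest beat i (5
  preceding, 5 following), truncated at record edges with the actual count
  as normaliser. (The printed formula in the source literature sums 11
  terms against a 1/10 factor; the 10-nearest-intervals reading is adopted
  as the consistent one.)
- `rr_ave`: mean interval over the whole record segment; exactly
  `(last R − first R)/N_RR` by telescoping.

All RR features are in seconds so trained models transfer across sampling
rates.

The Teager–Kaiser operator `NE[n] = x[n]² − x[n−1]·x[n+1]` is applied to
the 200-sample beat waveform (an RR-sequence variant exists as an option).
For a sinusoid `A·cos(Ωn+φ)` it is the constant `A²sin²Ω` — it scales with
amplitude *and* frequency, which is what makes it sensitive to fast
abnormal activations. The average `ANE` divides the sum of the N−2
interior NE values by N (the conventional printed normaliser; `"n-2"`
switches to the interior count). ANE scales exactly as `k²` under `x → kx`.

The feature vector is `[a4-ICA ×6, d4-ICA ×6, rr_pre, rr_post, rr_local,
rr_ave, ane]` — 17 values per beat.

## Classifier

A feedforward network with 10 ReLU hidden layers of 50 neurons and one
sigmoid output unit per class, trained by mini-batch SGD (batch 32, 200
epochs) on cross-entropy against one-hot targets. Features are z-scored
with training-fold statistics (RR seconds ~0.8, ICA projections ~1, ANE
~1e-3 live on very different scales). Weights use variance-scaled (He)
uniform initialisation from a seeded generator; training is bit-for-bit
deterministic for a fixed seed, and with `batch_size=None` (full batch,
exact mean gradient) it is additionally invariant to training-row order.
The per-epoch loss trace is recorded but not asserted monotone.

The default learning rate is 0.05. The reference configuration of this
architecture reports a grid-searched rate of 0.63
(`NetworkConfig.published_lr`); with standardized inputs and plain SGD
that rate is typically divergent, so it is preserved as a preset rather
than a default. Whether "limited to 50 neurons" means exactly or at most
50 is not specified anywhere; all layers use exactly
`neurons_per_layer` (configurable).

## Evaluation protocols

- **Class-oriented**: the 18 fine-grained symbols are the labels.
- **Subject-oriented**: labels are first collapsed onto the five ANSI/AAMI
  EC57 superclasses (N ← N,L,R,e,j; S ← A,a,x,J,S; V ← V,E,!; F ← F;
  Q ← Q,f,/,|). Despite the name, this protocol uses the same beat-level
  splits as the class-oriented one — it does not hold out whole
  subjects. A genuine record-holdout splitter (`holdout_records`) is
  provided separately for honest generalisation studies.

"3-fold cross-validation" is implemented as described by the protocol:
three *independent* stratified random 70/30 subsamplings (not a
partition-based k-fold, which is available as `make_kfold_partition`).
Per class, `floor(0.7·count)` beats train (minimum 1 per side); the
sparse atrial-escape class `e` uses 0.5. Classes with fewer than 2 beats
are excluded with a warning. Because of per-class flooring, the two
labelings can have test sets differing by a few beats on the same data.

Per-class metrics are one-vs-rest in percent: Se = TP/(TP+FN),
Sp = TN/(TN+FP), PPV = TP/(TP+FP), Acc = (TP+TN)/total (the per-class
accuracy definition on a multi-class problem is one-vs-rest by this
package's reading). Zero-denominator ratios are reported as NaN with a
note and excluded from averages. Overall accuracy is trace/total of the
confusion matrix.

## Synthetic data generator

Each beat class is a sum of Gaussian bumps for P, Q, R, S, T (an
ECGSYN-like parameterisation): per-class wave amplitudes and widths, P-wave
presence, mean RR and jitter, and a `pre_rr_factor` that multiplicatively
shortens (premature classes A, a, J, V, S, x) or lengthens (escape classes)
the interval preceding a beat of that class. Defaults encode textbook
distinctions — wide QRS for ventricular beats, absent P for
junctional/ventricular classes, a narrow tall pacing spike for paced
beats — and are pairwise distinct across the 18 classes. Records add the
rendered beats on a timeline (annotations mark the rendered waveform's
true maximum), then sinusoidal baseline drift (default 0.3 Hz, the upper
edge of the baseline-wander band, amplitude 0.1) and white Gaussian noise
(s.d. 0.02, ~2% of the R amplitude — mild electrode noise). One seeded
generator drives shuffle → RR jitter → noise in a fixed stream order, so
identical configurations are bit-identical and configurations differing
only in drift amplitude place beats identically.

What it emulates: annotated R-peaks at 360 Hz, class-specific morphology
and RR dynamics, drift and noise. What it does not: intra-class
morphological variability between patients, non-stationary rhythms,
electrode artifacts, class imbalance of clinical archives. Passing the
end-to-end test therefore demonstrates that the pipeline's machinery —
segmentation, features, leakage-free fitting, classification, metrics — is
correct and that well-separated classes are recovered (≥95% required,
~99.9% observed); it does not certify clinical-grade accuracy on real
archives, which depends on data the package does not ship.

## Problem sizes and defaults

The shipped experiments use sizes chosen to exercise every code path while
staying desk-scale: the end-to-end study uses 6 well-separated classes ×
300 beats (1800 beats, three 70/30 repeats); the all-class fixture uses 30
beats per class (4 for `e`, mirroring its scarcity); ICA oracles use 2000
samples of a known 6-source mixture; subband-edge crossovers are measured
on 2048-sample sinusoids by bisection (measured 11.20 and 22.47 Hz against
the analytic 11.25 and 22.5 Hz — within one FFT bin, reflecting the dmey
transition band).

## Known limitations

- The `dmey` coefficient count (69 per subband) is a consequence of filter
  length and boundary mode; protocols quoting "200 coefficients" for a
  200-sample beat are not reproducible with any standard extension mode.
- The WFDB reader covers the subset needed here (formats 16 and 212,
  single-channel extraction, MIT annotation decoding); it is not a general
  WFDB implementation.
- `remove_baseline` with the global mean leaves in-record drift; use the
  moving-average option for long ambulatory records.
- The MLP is CPU/numpy; it is deliberately small and deterministic rather
  than fast or GPU-capable.
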