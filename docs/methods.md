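# Methods

## Signal model and preprocessing

A recording is a sequence of tablet samples (t, x, y, pressure,
azimuth, altitude, pen state) with strictly increasing timestamps at a
nominal 200 Hz. The pen-state channel is authoritative: segmentation
into alternating pen-down (on-surface) and pen-up (in-air) strokes uses
it alone, and files whose pressure disagrees with it (positive pressure
in air, zero on surface) are repaired toward the pen state with a
logged warning.

Polar channels use the centroid of the pen-down samples as origin. The
true centre of an Archimedes spiral is unknowable from the drawing
without a fit, and the centroid is translation-robust; the cost is a
systematic offset of about one spiral pitch, which appears in the
modulus R as a once-per-revolution ripple. Feature statistics are
insensitive to it; the tremor-band diagnostics (`detrended_radius`)
remove it explicitly by regressing R on {1, Z, cos Z, sin Z} before
spectral analysis.

Kinematic channels are central finite differences on the recorded
(possibly non-uniform) time grid, one-sided at segment endpoints:
speed v = |(dx/dt, dy/dt)|, acceleration magnitude a, tangential
acceleration a_t = dv/dt, radius of curvature
ρ = v³ / |v_x a_y − v_y a_x| and centripetal acceleration a_c = v²/ρ.
ρ is capped at 10⁶ device units (straight-line limit) so every derived
channel is finite for every valid recording. In-air channels use the
recorded pen-up samples as-is, with no interpolation across gaps.

Spectra are one-sided amplitude spectra of the mean-removed,
Hann-windowed signal, zero-padded to a power of two. Spectral
*features* are evaluated on a fixed 512-point grid (0.39 Hz resolution
at 200 Hz) via interpolation, so the same feature indexes the same
frequency in every recording regardless of drawing duration.

## The linear catalog (186 features)

The catalog is declarative configuration (`CatalogSpec`), shipped as:
3 time features + 5 on-surface pressure statistics + 8 spatial
channels × 2 segments × 4 statistics (64) + 7 kinematic channels × 2 ×
4 (56) + zero-crossing rates of {x, y, pressure, R, v, a} per segment
(12) + the 23 lowest non-DC spectral magnitudes of x per segment (46)
= 186. The choice of ZCR channels and the number of spectral bins are
conventions of this package (the bins cover 0.39–9 Hz, bracketing the
4–12 Hz tremor band from below); `expected_total` guards the count so
any edit to the grid that changes it fails loudly. Zero-crossing rates
are counted on the mean-removed channel per second. A drawing with no
usable pen-up segment yields zero-valued pen-up features plus a
`missing_up` flag rather than an error, keeping the matrix rectangular.

## Non-linear features

**Higuchi FD.** Curve lengths L_m(k) are computed for scales
k = 1..kmax (default 8) and all offsets, normalised by the number of
actual increments, averaged over offsets, and FD is minus the slope of
log L(k) against log k. A constant window returns 1.0 (smooth-line
convention). kmax = 8 balances bias and variance at the default window
length.

**Castiglioni FD.** Katz's ratio formula with ordinate-only distances:
L = Σ|ΔX|, d = max|X_i − X_1|, n = N − 1, FD = log n / (log n +
log(d/L)). Constant and monotone series return 1.0. When d/L is so
small that the denominator is non-positive the formula leaves its
validity domain; the estimate saturates at 10 rather than diverging, so
feature vectors stay finite. The estimator is affine-invariant because
L and d scale together.

**Shannon entropy.** Equal-width histogram over [min, max] with 16
bins by default, H = −Σ p̂ᵢ log₂ p̂ᵢ in bits (0 ≤ H ≤ 4).

All three run over sliding windows of 128 samples (0.64 s at 200 Hz —
four to eight tremor cycles) with 50% overlap, and the per-window
profile is summarised by min/max/mean/median; tremor waxes and wanes,
and the extremes of the profile carry information the whole-signal
value averages away. Segments shorter than the four-window minimum
degrade gracefully to a single whole-segment window; segments under 16
samples yield zeros with a flag. Per FD estimator the extractor emits
3 channels × 2 segments × 4 aggregates = 24 features plus the
whole-recording FD of each channel (3), i.e. 27; entropy emits
3 channels × 4 aggregates over the full signal, i.e. 12. The local
peak-distortion score (prominent extrema per second) is available as an
auxiliary measure but is deliberately outside the counted catalogs.

## Selection and classification

Each feature is tested with the unbalanced one-way ANOVA F statistic
(explicit between/within sums of squares; p from the F distribution);
features with p < 0.05 are kept, with no multiple-testing correction —
selection here is a screening step, not an inference claim. Constant
features get p = 1. By default selection runs once on the full cohort
before cross-validation, mirroring the two-stage reference protocol;
`--per-fold-selection` re-selects inside every training fold for a
leakage-free estimate.

Classifiers (scikit-learn, standardised inside each training fold):
SVM with polynomial kernel of degree 1 and C = 1; an MLP with one
hidden layer of NNHL = max(n_features, n_classes) units trained for
NNHL × 10 epochs (the arithmetic-mean rule is selectable — the NNHL
formula in the source literature is ambiguous); 1-NN with Euclidean
distance. Folds are stratified with seeded shuffling; pooled fold
predictions give Acc, CER = 100 − Acc (an exact identity), per-class
accuracy and the confusion matrix. Coverage95 is the percentage of
rows whose true class lies in the smallest predicted-probability class
set reaching 0.95; for the margin-based SVM the probability is a
logistic link on the decision value, an approximation of fully
calibrated scores. ACCER is the plain sum of CERs (or per-class error
rates) over a list of experiments.

## Synthetic cohort

The generator emulates the spiral-drawing task, not hand biomechanics.
Ideal trajectory r(θ) = a + bθ (a = 100, b = 130 device units,
5 turns) drawn at a constant 2.6 rad/s (≈12 s per drawing) and sampled
at 200 Hz. Tremor is injected radially — the direction in which
spiral tremor is conventionally scored — as
A(t)·sin(φ(t)) with instantaneous frequency f₀(1 + jitter·AR1) and
amplitude A₀(1 + mod·AR1). Pressure is 512 ± AR(1) noise (std 3
device units on a 10-bit scale); pen lifts are Poisson-placed pen-up
intervals of exponential duration with a small outward in-air loop and
zero pressure; azimuth/altitude are bounded random walks present only
so the full catalog is exercised.

The default cohort is 27 control and 24 ET drawings. Controls carry
micro-tremor at the noise scale (amplitude 3); the ET default is the
documented strong-effect condition, amplitude 60 = 20× the noise
scale, with per-subject amplitude dispersion of 15% and frequency
dispersion of 1 Hz clipped to 4–12 Hz. These are conventions chosen to
be realistic in ratio, not estimates of any clinical cohort: absolute
tablet scales of clinical data are unpublished. Consequences for
interpretation: passing end-to-end tests shows the pipeline recovers a
radial-sinusoid tremor of known band and amplitude ratio; it does not
certify performance on real drawings, where tremor is non-sinusoidal,
amplitude scales differ, and class overlap is far larger.

The amplitude-monotonicity check sweeps ET amplitude over
{4, 8, 16, 32, 64} device units across 10 cohort seeds, using reduced
12 + 12-subject, 3-turn cohorts with the linear catalog and the 1-NN
classifier, and computes the Spearman correlation of the per-amplitude
mean accuracy; the mean curve is used because individual small-cohort
accuracies are noisy and tie at saturation.

## Numerical conventions and edge cases

* SVC timestamps: integers are milliseconds, floats are seconds;
  normalised internally to seconds from zero. Values on the millisecond
  grid are written back as integers, making write∘read a fixed point of
  the text form.
* Device units are never converted to millimetres; no filtering or
  resampling is applied anywhere in the pipeline.
* Higuchi scales with zero curve length are dropped from the log-log
  fit; if fewer than two scales remain the estimate is 1.0.
* ANOVA refuses groups with fewer than two rows and non-finite
  features, naming the offender.
* All randomness (generator, fold shuffling, MLP initialisation) flows
  from explicit integer seeds; identical seeds give bit-identical
  outputs, which the tests assert.

## Known limitations

* The in-air trajectory of real drawings reflects motor planning; the
  generator's pen-lift loops are morphological placeholders only.
* Coverage95 for the SVM uses an uncalibrated logistic link; with few
  samples its probabilities are optimistic.
* Full-cohort selection before cross-validation leaks label information
  into the S-sets by design (it mirrors the reference protocol); use
  the per-fold mode for unbiased error estimates.
* Castiglioni FD values are not confined to [1, 2] for noise-like
  windows; within this pipeline they act as a discriminative index, not
  a geometric dimension estimate.
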