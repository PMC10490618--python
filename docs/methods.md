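# Methods

This note records the models, estimators and design choices behind
`imupipe`, the assumptions they make, and what the synthetic-data tests do
and do not demonstrate.

## Signal model and conventions

Recordings are bundles of timestamped channels in sensor-native units
(m/s² for acceleration, rad/s for angular rate, µT for magnetic field,
normalized amplitude for audio, degrees for GPS).  Internally, timestamps
are seconds from recording start, intervals are half-open, indexing is
0-based, and the device frame is x-right, y-forward, z-up (right-handed).
All inertial channels are linearly interpolated onto one uniform grid over
their overlapping span; the default rate is **40 Hz** (the nominal rate of
common smartphone IMU logging; the resampler is configurable).  Audio keeps
its native rate and is framed independently.

Headings use an ENU-style yaw: positive counterclockwise, zero when the
device +x axis points at magnetic north while level, wrapped to (−π, π].
`atan2` is used wherever a quadrant-blind arctangent would be ambiguous.

## Denoising

Each IMU channel passes through a second-order Butterworth low-pass applied
forward and backward (`sosfiltfilt`), so the phase is exactly zero and the
effective magnitude response is the squared single-pass response.  Zero
phase matters here: a causal filter's group delay would shift step peaks
and heading onsets relative to the labels.  The library function defaults
to a normalized cutoff of 0.001 (a near-DC smoother); the *pipeline*
default is a **10 Hz** cutoff at fs = 40 Hz, which suppresses wideband
sensor noise while passing gait fundamentals (≤ 4 Hz) and their first
harmonics.  Tests validate the implementation against the analytic digital
Butterworth magnitude `1/√(1 + (tan(πf/2)/tan(πf_c/2))^4)` rather than
against a frozen output.

## Windowing and stacking

Signals are cut into non-overlapping 5-s windows; three consecutive windows
form a stack, and stacks slide with a stride of one window (maximizing
training examples; both configurable).  The Hamming taper is applied to
*copies* used by spectral features; time-domain features (step detection,
heading) consume untapered samples, because tapering attenuates peak
amplitudes near window edges and would bias step timing.  The taper is
evaluated at `min(n, N−1−n)` so symmetry holds bitwise, not just to
rounding.

## Activity features

Per window, channel and axis (18 slots; 486 per stack):

* **Maximum Lyapunov exponent** (nats/sample) via Rosenstein's small-data
  method: delay embedding (delay = first autocorrelation zero crossing;
  embedding dimension from the false-nearest-neighbor estimate, capped at
  5 for 200-sample windows), nearest neighbors outside a mean-period
  temporal exclusion, mean log divergence over 8 steps, line fit over the
  first 5.  The fit range is short because a 200-sample window saturates
  quickly; on the r = 4 logistic map the estimator recovers ln 2 within a
  few percent.
* **MFCC**: Hamming-windowed frames → magnitude spectrum → triangular Mel
  filterbank → log (floored at 1e-10 so silence stays finite) → orthonormal
  DCT-II; the per-stack feature is the frame mean.  IMU channels use 1-s
  frames with 0.5-s hop and 20 filters — at 40 Hz, audio-style 25-ms frames
  would contain a single sample.  Audio uses the standard 25/10 ms framing
  with 26 filters.  13 coefficients are kept in both cases.
* **Fractal dimension** via Higuchi's estimator with k_max = 10.
* **Embedding dimension** via Kennel's false-nearest-neighbor criteria
  (rtol = 15, atol = 2, threshold 1%).  Distances at machine precision are
  excluded from the ratio test: exact repeats of a periodic signal are true
  neighbors, and the ratio of two rounding errors is noise.
* **Skewness** and **excess kurtosis** (population moments; Gaussian → 0,
  stated in the layout manifest to avoid convention confusion).

Degenerate (zero-variance) inputs map to fixed finite defaults (exponent 0,
dimensions 1, moments 0); no NaN or Inf leaves the module.

## Localization features

* **Steps.** The acceleration magnitude's mean is subtracted (removing
  gravity); the detection threshold is mean(|net|), since the literal mean
  of the net signal is zero by construction (mode configurable:
  `abs_mean | zero | quantile`).  Peaks closer than 0.25 s — a 4 Hz
  physiological cadence cap — keep the larger.  A scale-invariant **rest
  gate** suppresses detection when mean(|net|)/mean(|magnitude|) < 2%:
  without it, a stationary subject's sensor noise yields spurious
  supra-threshold peaks.  Both threshold and gate are self-ratios, so
  detection is exactly invariant to positive amplitude scaling.
* **Step intervals** are valley-to-valley times around each peak (the
  nearest local minima each side); a boundary peak with no valley on one
  side gets an absent interval.  The quantity is deliberately named
  *interval* (seconds), not length (meters).
* **Heading.** Roll/pitch come from the gravity direction, yaw from the
  tilt-compensated magnetometer (`H_M`); body rates are mapped to Euler
  rates, converted to an incremental rotation quaternion per sample, and
  composed into a running unit quaternion whose yaw is the gyro heading
  `H_G = atan2(2(q₀q₃+q₁q₂), 1−2(q₂²+q₃²))` — a bare ratio of those terms
  is not an angle and diverges at ±90°.  The fused heading is the circular
  mean of `H_M` and `H_G` (an arithmetic mean breaks at the ±π wrap);
  antipodal inputs fall back to the gyro heading.  The accelerometer and
  magnetometer are low-passed at 0.5 Hz before the attitude computation:
  gravity and the earth field are quasi-static, and feeding gait linear
  acceleration into the tilt estimate rectifies into a yaw-dependent
  compass bias.  Per-stack summaries are the circular mean/std of the fused
  heading and the net change between 1-s endpoint means (single-sample
  endpoints carry noise and filter edge transients).
* **Audio / GPS.**  Audio MFCC frame means plus a presence flag (zeros when
  absent — a missing optional channel is flagged, never imputed); GPS
  contributes an availability flag and mean ground speed from a local
  equirectangular projection.

## Selection and augmentation

Recursive feature elimination fits an L2-regularized logistic regression on
the standardized surviving features, ranks by the coefficient-column norm,
and drops the bottom ⌈5%⌉ per iteration until the target count (default:
50% per bank) remains; exact ties drop the higher index.  The elimination
loop is in-package so the tie rule and step size are exact; the ranker is
scikit-learn's.

Augmentation crosses each vector with a freshly drawn same-class partner by
swapping middle thirds (boundaries ⌊L/3⌋ and L−⌊L/3⌋), ten generations per
vector, multiplying the corpus by eleven.  Same-class partners are the
default because cross-class hybrids inheriting the first parent's label
would inject label noise.  Note that with a pure middle-third swap,
chaining offspring is algebraically identical to crossing the original each
time (outer thirds persist; the middle is always the newest partner's), so
the `chained` flag affects provenance only.  Augmentation is applied to
training folds only — crossing before the split would leak test
information into training offspring.

## Deep neural decision forest

The embedding network (rectifier layers, default 512–256, then a linear
128-dimensional output) feeds every tree; each internal node routes left
with probability sigmoid(w·z + b); each leaf holds a softmax class
distribution; the prediction is the routing-weighted leaf mixture averaged
over trees (default 10 trees of depth 6).  All parameters are trained
*jointly* by mini-batch Adam on the negative log-likelihood — chosen over
alternating leaf/routing optimization for simplicity; both reach the
fixtures' accuracy.  Features are standardized with training-split
statistics.  Untrained leaves are exactly uniform; leaf-reach probabilities
sum to 1 by the telescoping product identity, which tests verify to 1e-6.
The implementation is plain numpy with hand-derived gradients (verified
against numerical differentiation to ~1e-8); model sizes here make a CPU
epoch over a few thousand vectors a fraction of a second.  The input width
is taken from the feature layout at run time; a 740-wide layout is honored
when the configuration produces one, but nothing hard-fails on other
widths.  Activity and location use two independent instances — "parallel"
is read as task-parallel, not weight-sharing.

## Evaluation

Stratified 10-fold cross-validation, grouped by recording so stacks cut
from one recording never straddle the train/test boundary (subject-disjoint
folds would be the stricter alternative; with the synthetic corpus each
recording is its own subject, so the two coincide).  Selection and
augmentation are fitted inside each training fold.  Metrics are the
confusion matrix (raw and row-normalized) and per-class
precision/recall/F1 via scikit-learn, cross-checked in tests by a
hand-rolled counter.

## Synthetic data: what it shows and what it does not

The generator emulates the *structure* of wearable recordings: gravity plus
an activity-specific gait sinusoid (walking 2.0 Hz / 1.5 m/s², running
2.8 Hz / 4 m/s², sitting 0.3 Hz postural sway, standing 3–8 Hz tremor),
a piecewise-constant yaw-rate schedule integrated consistently into the
gyroscope and the rotated earth field (22 µT horizontal, −42 µT vertical),
location-specific audio spectra (pink/white/band-passed noise) and GPS
tracks for outdoor scenarios.  Per-recording parameters are jittered ±10%;
all randomness flows from one seed through `numpy.SeedSequence`.

Passing tests therefore demonstrate *internal consistency* — the pipeline
recovers step counts, net heading changes and class identities that the
generator planted, within stated tolerances — and *correctness of the
estimators* against analytic oracles.  They do not demonstrate accuracy on
real in-the-wild corpora, whose label noise, device placement variation and
non-stationary behavior the generator deliberately does not model; the
dataset adapters exist so real corpora can be substituted when available.

## Numerical choices and degenerate inputs

* filtfilt pad length is capped at n−1 so short-but-valid inputs filter.
* Circular std uses √(−2 ln R) of the resultant length, clipped for R → 0.
* Quaternions are re-normalized every step; norm drift stays below 1e-9
  over 10⁴ steps.
* Argmax ties in prediction resolve to the lowest class index; RFE
  importance ties drop the higher feature index.
* Routing sigmoids are clipped to [1e-7, 1−1e-7] before logs.
* Problem sizes in tests and the acceptance script (2000-sample oracle
  series, 100-recording corpus, 10-fold CV) were chosen as the smallest
  sizes at which the estimators' known asymptotic values are cleanly
  resolved.

## Known limitations

* The heading pipeline assumes a roughly level device; large sustained
  tilts excite Euler-rate singularities near ±90° pitch.
* Step detection is cadence-gated (0.25 s refractory) and will undercount
  pathological gaits above 4 Hz.
* The GA operates on vectors after selection; offspring are convex in
  neither parent (hard segment swap), which preserves marginals but can
  create implausible joint combinations — by design, mirroring the
  augmentation it implements.
* No GPS map-matching, dead-reckoning trajectory reconstruction, or
  adaptive window sizing.
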