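# Methods

This note records the models implemented in `eegmci`, the parameter
choices that matter, the numerical decisions taken where the construction
was genuinely open, and what the synthetic-data validation does and does
not establish.

## Data model and preprocessing

A recording is a channels × samples array of microvolt amplitudes with its
sampling rate, the 19 canonical 10–20 labels (Fp1 … O2), a subject id and
a class label (MCI / HC / UNKNOWN).  Band-pass filtering uses a 4th-order
Butterworth design applied forward–backward (`sosfiltfilt`), i.e. zero
phase: the family and order are standard EEG practice and preserve
waveform morphology; the 0.5–32 Hz defaults bracket the delta-to-beta
range and reject EMG and line interference.  Note the 0.5 Hz high-pass
edge rings for a few seconds at the recording boundaries — steady-state
attenuation figures apply away from the edges.  Segmentation takes
`floor(N / window)` non-overlapping windows (default 60 s) and discards
the partial tail; segments inherit the subject's id and label.

## Spectral features

Welch PSD with a Hamming taper, 512-sample windows (2 s at 256 Hz — at
least two cycles of the lowest theta frequency) and 50 % overlap, density
normalization (the PSD integrates to the signal variance).  Band power is
the trapezoidal integral over the half-open interval [lo, hi), so shared
edges are never counted twice.  Four bands are used — delta [0.5, 4),
theta [4, 8), alpha [8, 13), beta [13, 32) — giving 76 band powers; the
delta low edge matches the filter cutoff.  Interhemispheric asymmetry is
the natural-log power ratio of the eight right–left homologous pairs per
band (32 features); natural log is the signal-processing default and any
other base only rescales the feature.  Total: 108 spectral features.

## Synchronization likelihood

Both signals are time-delay embedded (dimension m, lag l).  For reference
time i, the critical distance ε_{k,i} of channel k is the distance to the
⌈p_ref·W⌉-th nearest neighbour among the W temporally valid indices j with
w1 < |i−j| < w2 — the exact rank-statistic solution of "the fraction of
valid neighbours within ε reaches p_ref", with the Theiler window applied
on both sides of i.  SL for a pair is the probability, conditional on one
channel recurring at (i, j), that the other channel also recurs, averaged
over reference times and both channels.  The conditional (recurrence-count)
normalization is what makes the estimator land on its documented limits:
exactly 1 for identical signals, expectation ≈ p_ref for independent ones
(the discrete expectation is ⌈p_ref·W⌉/W, e.g. 0.0113 for p_ref = 0.01 and
W = 618; a window-size normalization instead would pin even identical
signals near p_ref).  Defaults: p_ref = 0.01, l = m = 10, w1 = 100,
w2 = 410 samples.  Distances are Euclidean; per-channel affine rescaling
leaves SL unchanged because ε is a rank statistic of each channel's own
distances.  The 171 pairwise values (C(19,2); the diagonal is not
computed) are evaluated from per-channel recurrence masks computed once
and AND-ed per pair, so the full matrix costs little more than the 19
critical-distance searches.  A `stride` parameter subsamples reference
times for long segments; stride 1 is the reference computation and the
striding only thins the outer average, never the neighbour window.

## Nonlinear descriptors

One value per channel; 8 × 19 = 152 features.  Slope-based estimators
need scale/scaling-region choices that no closed formula dictates; the
defaults below are deliberate algorithm parameters.

- **DFA.** Integrated profile, non-overlapping windows, per-window linear
  detrend, RMS fluctuation (the root-mean-square form; a non-squared sum
  does not define a fluctuation), slope of log F(n) vs log n over ≥ 10
  log-spaced scales from 4 to N/4.  White noise → 0.5, Brownian → 1.5.
- **Higuchi FD.** Curve lengths with the standard end-correction, averaged
  (not summed — a constant factor that leaves the slope unchanged) over
  offsets, slope of ln L(T) vs ln(1/T) for T = 1…30.  Line → exactly 1,
  white noise → 2.
- **Correlation dimension.** Grassberger–Procaccia correlation integral
  with Theiler exclusion (one delay), delay from the first autocorrelation
  zero (capped at 20), m = 1…10, slope over the central 50 % of the log-r
  span between the 1st and 50th distance percentiles; saturation declared
  when successive slopes agree within 5 %.  The orbit is evenly strided to
  ≤ 1200 points to bound the quadratic cost.  Caveat: a periodic signal
  sampled commensurately with its period yields a lattice of embedded
  points and a gap in the distance distribution that no scaling-region
  rule can bridge; dimension checks use incommensurate sampling.
- **Largest Lyapunov exponent.** Rosenstein method: nearest neighbour with
  temporal separation beyond the signal's mean period (dominant spectral
  peak, capped at a tenth of the orbit so 1/f-dominated signals keep
  admissible neighbours), mean log divergence over the horizon, slope of
  the initial region (fit stops 0.5 nats below the saturation plateau).
  Reported per sample.  Logistic map (r = 4) → ln 2.
- **C0-complexity.** Spectral components whose squared magnitude strictly
  exceeds the mean squared magnitude form the regular part; C0 is the
  residual-to-total power ratio.  The strict inequality makes a perfectly
  flat spectrum (impulse) give exactly 1.
- **Kolmogorov entropy.** The defining triple limit is not computable from
  finite data; the Grassberger–Procaccia K2 correlation entropy
  (1/(Δm·τ))·ln(C_m/C_{m+Δm}), median over the central scaling region and
  clipped at 0, is the practical estimator (a lower bound on the KS
  entropy).  Periodic signals → ≈ 0, logistic map → ≈ ln 2.
- **Shannon entropy.** 16 equal-width amplitude bins over [min, max],
  empty bins skipped, natural log; constant signals give 0 by convention.
- **Approximate entropy.** Pincus construction, Chebyshev distance,
  self-matches included (so pattern frequencies are strictly positive and
  a constant signal gives exactly 0); m = 2, r = 0.2 × SD.  The tolerance
  follows the universal SD convention; a `r_mode="var"` switch restores a
  literal 0.2 × variance.

`nonlinear_feature_vector` truncates channels to `max_samples` (default
4096) before estimation to bound the quadratic-cost descriptors; pass
`None` for full segments.

## Selection, classification, validation

Features are concatenated in the fixed order connectivity (171), spectral
(108), nonlinear (152) — 431 in all.  z-scoring uses training-fold means
and sample (n−1) standard deviations; constant training columns map to
zero.  SBFS starts from the full set, removes the feature whose removal
maximizes J (mean LDA accuracy under internal stratified k-fold CV,
k = min(10, smallest class count), seeded folds), accepts only strict
improvements, and — in the floating variant, the default — conditionally
re-admits earlier-removed features (never the one just removed) while that
helps.  Ties break toward the lowest column index, making runs
reproducible.  The selected subset is refitted inside every outer training
fold, never globally, which is what the leakage audit (hash of scaler
statistics + selected columns against a refit on training rows alone)
verifies.

Classifier families map to scikit-learn estimators with fixed, sensible
defaults (linear SVM C = 1; RBF SVM C = 1, γ = "scale"; k-NN k = 5;
gradient boosting for the gentle-boosting family).  The random-
undersampling boosting family is a small wrapper that balances classes by
seeded undersampling before AdaBoost.  No hyperparameter search is
performed.

Metrics (MCI positive): AC, SE, SP, F1 as usual.  FDR defaults to
FP/(FP+TP) — the conventional false-discovery rate, consistent with the
reference confusion-matrix example (1/17 = 5.9 %) — while `fdr_mode="eq27"`
computes FP/(FP+TN) for the alternative printed definition (1/16 = 6.25 %
on the same counts).  10-fold CV is stratified with a required seed; LOPO
CV extracts features from whole unsegmented recordings so no participant
contributes samples to both sides of any split, and accumulates one
confusion count per held-out subject.  Group analyses use per-feature
two-sample t-tests (pooled variance) with deterministic p-then-name
ranking.

## Synthetic cohorts

Each subject's channel is a sum of four band oscillations (carriers at 2,
6, 10, 20 Hz, ±10 % per-subject frequency jitter, random phases) plus
1/f^1 background noise (spectrally shaped white noise, 10 µV RMS).
Default group contrasts follow the usual MCI-versus-control EEG picture:
lower alpha (12 vs 20 µV) and beta (4 vs 6), mildly higher theta (11 vs
8), equal delta, and weaker coupling (0.2 vs 0.6) on the fronto-central
pairs F3–C3 and Fp1–F3.  Coupling mixes a shared latent source z into a
pair as (1−c)·own + c·z, with z lagged 10 samples on the second channel
(matching the SL embedding lag): c = 0 gives independent channels,
c = 1 an exactly lagged copy, and SL rises monotonically in between.
Cohort size defaults to 18 MCI + 16 HC.

What the generator does *not* emulate: volume conduction and realistic
forward-model channel covariance, artifacts (blinks, EMG, drift),
non-stationarity, or realistic effect sizes — the default contrasts are
deliberately strong so that recovery failures indicate implementation
errors, not statistical bad luck.  Passing tests therefore demonstrate
correctness of the estimators and protocol integrity (no leakage, no
selection optimism), not clinical-grade classification performance.

## Validation problem sizes

The validation suite runs each stage at sizes chosen to keep the full
suite in minutes on one CPU: SL unit tests use short signals and a reduced
parameter block (stride-1 results remain the reference), descriptor
known-answer tests use 2 000–5 000 samples, the null-cohort selection
audit uses 15+15 subjects × 60 s at 128 Hz with SBFS on the 19 alpha-power
features over 20 seeds, and the separability check uses 15+15 subjects
× 10 s at 256 Hz with connectivity (stride 8) + spectral features under
LOPO over 5 seeds.  `scripts/acceptance.py` re-runs the same computations
from scratch and reports the measured numbers.

## Known limitations

- SL cost grows linearly in segment length × window width; full 60 s
  × 256 Hz segments at stride 1 take tens of seconds per segment.
- The K2 and D₂ estimators assume a visible scaling region; heavily
  oversampled periodic signals or very short segments may not provide one
  (errors are raised rather than guessed around).
- EDF export is not provided (reading is, via `mne`); fixtures use CSV.
- The LOPO protocol requires one recording per participant; repeated
  sessions per subject are out of scope.
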