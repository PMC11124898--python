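# Methods

This note records the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite can show.

## Signal model and baseline correction

A MOS sensor's resistance falls when reducing gases adsorb on its heated
oxide surface. We work throughout in the relative-conductivity response

    x_t = R_air / R_S(t) = G(t) / G_0,

with `R_air` the arithmetic mean of the sensor's resistance over the 60 s
clean-air pre-clean window (the only clean-air segment recorded) and
`R_S(t)` the in-sample resistance. `x = 1` means no response. The ratio
form cancels any multiplicative rescaling of a record's resistances —
a property the tests exercise directly — and thereby part of long-term
drift.

Records follow the acquisition protocol: 1 Hz sampling, 60 pre-clean
points, 90 injection points, 90 cleaning points — 12 × 180 = 2160
response values per sample.

## Synthetic records

No public dataset exists for this problem, so the simulator is a
first-class, tested component; it defines the study conditions for every
stochastic claim the suite makes.

**Kinetics.** During injection the response rises as a saturating
exponential toward a class- and sensor-specific asymptote `A`:
`x(t) = 1 + (A − 1)(1 − e^(−t/τ_r))`, and during cleaning it decays as
`x(t) = 1 + (x(90) − 1)e^(−(t−90)/τ_d)`, with τ_r = 15 s and τ_d = 25 s.
The double-exponential adsorption/desorption form is the simplest model
matching the published curve shapes; with τ_r = 15 s the response reaches
99.75 % of its asymptote by the end of injection, so measured peaks agree
with the profile amplitudes to well under 1 %.

**Class profiles.** Per-class asymptotes for the 12 sensors follow the
published selectivity pattern: alcohol-sensitive sensors (S2, S5, S9)
respond to every grade with a rising trend; hydrogen/ketone sensors
(S1, S4, S8, S10) respond weakly to normal samples and strongly to rot;
the sulfide sensor S3 and the high-detection-limit alkane sensors
S11/S12 respond mainly to total rot. Three anchors are quantitative:
S4 = (1.11, 1.27, 2.05) and S5 = (1.39, 1.73, 2.67) in laboratory mode,
S8 = (1.71, 2.01, 3.03) in storage mode. Storage-mode profiles elevate
normal and slightly-rotten responses more than totally-rotten ones
(the reported pattern), compressing — but never inverting — the class
ordering.

**Stochastic terms.** Four per-sample terms, all seeded:

| term | form | laboratory | storage |
|---|---|---|---|
| ambient offset | additive conductivity response with its own slower kinetics (τ 25/40 s); amplitude `scale·exp(0.15·G + 0.15·Z_s)`, lognormal, shared factor G per sample, independent Z_s per sensor | scale 0.02 | scale 0.45 |
| concentration spread | lognormal factor shared across sensors multiplying `(A − 1)` | σ 0.05 | σ 0.25 |
| amplitude spread | per-sensor lognormal factor on `(A − 1)` | σ 0.08 | σ 0.08 |
| measurement noise | i.i.d. Gaussian per time point | σ 0.01 | σ 0.02 |

The ambient term is class-independent and *kinetic*: background gases are
pumped in with the sample stream, so a constant offset would be invisible
to difference and spectral features. Its lognormal sigmas are small so
that class-range endpoints stay orderly — with heavy tails the extreme
sample of one class dominates every range and the overlap geometry
degenerates. The shared concentration factor models how much headspace
gas actually reaches the chamber: tightly controlled by the laboratory
protocol, highly variable in storage (box loading, temperature, airflow).
It moves a sample along its own class's response direction, which is the
irreducible confusion that degrades storage-mode accuracy. The storage
values were calibrated once so the classical baselines reproduce the
reported qualitative degradation (k-NN worst in storage, mid-80s for
SVM/LR, discretization recovering k-NN) and then frozen; the paper
reports no variance information, so these spreads are the package's own
defaults, documented here, not claimed from the source study.

**What the simulator does not emulate.** Real cross-sensitivity
nonlinearities and sensor saturation, humidity/temperature effects,
multi-session drift, and correlated VOC chemistry between sensors. A
passing suite therefore shows the *pipeline* behaves as designed under
the stated interference model — not that the specific accuracies carry
over to a physical array.

## Features and normalization

Per sensor: F1 mean, F2 max, F3 injection-phase sum (t = 0..T_b, T_b = 89
0-based), F4 mean over [T_a, T_b] with T_a the first index attaining the
injection-window maximum (earliest-index tie-break), F5/F6 max/mean
forward difference (Δt = 1 s), F7 max second difference, F8–F12 the five
largest magnitudes of the unnormalized length-180 FFT, one-sided, DC bin
excluded (DC duplicates F1 up to scale), sorted descending, no windowing
function. Features are computed on the baseline-corrected responses and
min–max normalized to [0, 1] with statistics fitted on the training split
only (fitting on all samples would leak test information); out-of-range
values clip, and degenerate constant columns map to 0 with a warning.

## Feature selection

The filter stage scores each feature by mixed mutual information,

    MIME(F_i) = I(F_i, y) − α·(1/m)·Σ_j I(F_i, F_j) − β·(1/m)·Σ_j I(F_i, F_j | y),

with j over the other m features, α = β = 1. MI is the plug-in estimator
on joint histograms after equal-frequency binning into 8 bins — chosen
over nearest-neighbour estimators because it is scale-robust and
verifiable exactly against a four-loop brute-force oracle (the suite
checks agreement to 1e-12). Features below the lower-quartile score are
dropped (never emptying the set).

The wrapper draws a not-yet-tested feature uniformly at random (seeded),
measures 5-fold cross-validated accuracy of an RBF SVM (C = 1) without
it, and deletes it permanently whenever accuracy does not decrease — ties
favour the smaller model — stopping once every remaining feature has been
tested since the last deletion. The selected-feature count is
data-dependent (typically 15–45 on synthetic storage data at 300
samples); the evaluation harness additionally floors the wrapper at 10
features so every CNN spec keeps a workable receptive field downstream.

## Class-overlap discretization

Per feature, each class's [min, max] is computed on the training split;
the endpoints strictly inside the global range become breakpoints, and
the K = breakpoints + 1 segments get 1-based left-to-right tags
(half-open [b_k, b_{k+1}) segments, last segment closed; out-of-range
values clip into the end segments, so the mapping is total and monotone).
Gap segments between disjoint class ranges keep their own tag, and
adjacent overlap segments with the same covering class-set are kept
distinct (the conservative choice). Tags are one-hot encoded; the encoded
features replace the raw ones wherever discretization is enabled.
Fitting on the training split only is a deliberate deviation from
computing ranges over all samples, which would leak test information.

## Ensemble CNN

A base classifier treats the feature vector (raw selection or one-hot
encoding) as a single-channel 1-D sequence: two valid-padded convolutions
with stride 2 and ReLU, flattened into a perceptron (n → 200 → 3) with
softmax output. The grid varies (kernel size, kernel count) of both
layers over [3,5,7,9]×[8,16,32,64] and [3,5,7]×[32,64,128] — 144 groups;
specs whose receptive field exceeds the input after striding are rejected
at validation. Grid search returns the validation-accuracy argmax, ties
broken toward fewer parameters then lexicographically. The default
ensemble is the optimal group (5,64)/(3,128) plus its 9 nearest feasible
grid points under L1 distance on grid-index coordinates.

Training is full-batch gradient descent on softmax cross-entropy at
learning rate 0.001 with "decay = 0.9" read as the momentum coefficient
(a per-epoch multiplicative lr decay of 0.9 would shrink the step by
10^-14 over 300 epochs; both readings are available via `decay_mode`).
Weights are Gaussian with He scaling; networks are float32 and training
is bit-for-bit reproducible from the seed. The default epoch budget is
300.

The meta-learner — one convolution (default kernel 3, 16 kernels, from a
3×5 grid) and one dense layer — reads the 10 × 3 concatenated base
probabilities. It is trained on out-of-fold base outputs (stacking; folds
within the training set) rather than in-sample outputs, which overfit
the bases' training optimism (`stacking="insample"` restores the naive
behaviour). Because the meta network is orders of magnitude smaller than
the bases, it gets its own epoch budget (800) large enough to reach its
loss plateau; undertrained meta-learners visibly fail to match even
majority voting.

## Evaluation protocol

60/10/30 % stratified train/validation/test splits; every model is run on
five seeded re-splits (re-splitting is the more conservative reading of
"trained five times"; a fixed-split mode exists). Baselines are standard
implementations with fixed settings: RBF SVM (C = 1), L2 logistic
regression, 5-NN — comparison plumbing, not contributions. Reports carry
per-cell accuracy mean ± std, the best run's confusion matrix (tie →
lowest seed), and the discretized-minus-raw delta column. Cell failures
are isolated, not fatal.

**Ensemble-vs-base comparison.** The "best single base" is the base
architecture with the highest *mean* accuracy across the repeated splits.
Comparing instead against the per-split hindsight maximum of ten
classifiers would build in an order-statistic bias of several accuracy
points on 90-sample test sets, which no fused ensemble — effectively a
weighted vote — can systematically beat.

## Problem sizes and numerical choices

The test suite and the acceptance script run the repeated-split protocol
at the package's desk scale: 100 samples per class, 5 splits, 60 epochs
for base networks (the loss plateaus there on these feature widths;
results at 120 epochs agree within split noise), 3 stacking folds
(measured indistinguishable from 5 on this data), meta epochs 800.
Oracle checks use ≥100 randomized small instances each. Tolerances:
MI vs brute force 1e-12 (identical arithmetic, different loop
structure); FFT vs direct transform relative 1e-9 (float64 rounding);
peak recovery 2 % (kinetic saturation shortfall is ≤0.25 %). Chance-level
checks use binomial error bands around 1/3.

## Known limitations

* The storage-mode interference model is one plausible mechanism
  (kinetic additive background + shared concentration spread); real
  storage air is less stationary and more correlated across sensors.
* Discretization helps the distance-based k-NN on average under this
  interference model and leaves the ensemble within noise, but the k-NN
  delta varies by several accuracy points across dataset draws (it is a
  difference of two noisy ~75 % accuracies on 90-sample test sets) and
  single draws with a negative delta occur. For SVM and logistic
  regression the delta is typically *negative* on synthetic data — raw
  margins let these models regress out part of the shared interference,
  which one-hot tags cannot. The reported all-positive storage deltas
  are not reproduced by this generator.
* Multi-session drift correction and humidity/temperature compensation
  are out of scope.
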