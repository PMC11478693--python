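# Methods

This note documents the models, estimators and design choices behind
`sensorqc`: what each quantity assumes, which knobs matter, what the
synthetic generator does and does not emulate, and where the numerical
corners are.

## Records and aggregation

The atomic unit is a *record*: a short, continuously sampled observation
(millisecond timestamps, one column per sensor channel). Records are
grouped per (participant, sensor); each of the eight quality metrics is
reduced to one value per group. Per-record metrics (MDR, SNR, APD, SRC,
SCR) aggregate by the **median** over records — medians match the
median/IQR summaries the metrics are reported with, and are robust to the
occasional catastrophic record; the mean is available via
`summarize_participant(..., aggregate="mean")`. Set-level metrics (IRLR,
RLC, VRC, the modal channel count behind SCR) are computed once per group.
Records failing a metric's precondition (fewer than 2 points for MDR/SNR,
3 for SRC, 20 for anomaly scoring) are excluded from that metric only;
they still count against IRLR, which is the metric that exists to expose
them.

All ratio-scaled metrics are min–max normalized pooled over sensors and
participants before cross-sensor comparison or classification; SNR keeps
its dB scale so sign and magnitude stay interpretable. Normalization is
idempotent and maps a constant column to zero.

## The data-driven sampling interval and MDR

The expected sampling interval of a record is the mode of its consecutive
timestamp differences, quantized to 1 ms (real clocks jitter; an
unquantized mode is degenerate). Duplicate timestamps contribute zero
intervals and are excluded from the mode — a zero modal interval would
make the gap test undefined. Ties between modal intervals break to the
smallest, the conservative choice that maximizes detected missingness.

A gap registers missing points only when it exceeds **1.1×** the modal
interval; the 10% tolerance keeps ordinary jitter from being counted as
missingness (at the default jitter levels this biases MDR by well under
0.01). MDR's denominator is observed + inferred-missing points, so
MDR ∈ [0, 1).

One structural caveat, inherent to a data-driven interval: a record that
loses every other sample becomes a slower regular grid and is
indistinguishable from clean data. Missingness is only *visible* when
sampling survives in runs — which field data does, and which the
synthetic generator reproduces by deleting in bursts.

## SNR and what "noise" means here

`SNR = 20·log10(MAV/σ)` treats the mean absolute value as signal and the
standard deviation as noise. Two consequences matter. First, the measure
is scale-invariant and unit-agnostic. Second, it is really a measure of
*peakedness*: any record with Gaussian marginals scores ≈ −1.96 dB
regardless of how noisy it "looks", and strongly negative values (−8,
−13 dB) are only possible for heavy-tailed records whose variance is
dominated by rare high-amplitude excursions. Channels are summarized by
the median; zero-variance channels cap at +120 dB, all-zero channels with
noise at −120 dB.

## Anomalous point density

Per-point decision scores come from a feature-bagging ensemble: `rounds`
(default 8) local-outlier-factor detectors, each on a random subset of
between ⌈d/2⌉ and d features. The per-channel features are the raw value,
the deviation from an 11-point rolling median scaled by the rolling MAD
(a *local* z-score), and the smaller-magnitude of the backward/forward
first differences of that local z (an impulse indicator that stays small
at the point after a spike). Local scaling is what keeps quiet-region
anomalies visible inside non-stationary, burst-dominated noise.

Per-round scores are normalized in two regimes before averaging:

- ranks are mapped through the inverse normal CDF (van der Waerden
  normal scores), which Gaussianizes the bulk. This is what calibrates
  the `mean + 3σ` threshold: on clean records ~0.2% of points exceed it
  (the tail of a Gaussian sample), whereas raw standardized LOF scores
  are leptokurtic enough that 1–2% of perfectly clean points would be
  flagged, and bounded plain ranks can push the threshold beyond their
  maximum so that nothing is ever flagged;
- scores far beyond the bulk (more than 60 bulk-IQR units above the
  median) additionally carry an unbounded, log-compressed magnitude term,
  so gross anomalies still clear the threshold when their own presence
  inflates σ(DS).

The neighborhood size is k = 60 (capped at RL−1): k must exceed the size
of a plausible anomaly cluster or dense anomaly sets mask themselves as
each other's neighborhood. For records longer than 500 points the
detector density is fitted on a 500-point subsample and all points are
scored against it, which changes measured APD by well under 10⁻³ while
bounding the cost of long records. APD can never exceed 1/9 by
Chebyshev's inequality applied to the z-threshold.

## Consistency scores

`2·(1 − sigmoid(cv))` maps a coefficient of variation to (0, 1], equal to
1 exactly at cv = 0 and strictly decreasing. It is evaluated as
`2·sigmoid(−cv)`; the textbook form cancels to exactly zero in double
precision near cv ≈ 37. The cv uses the population standard deviation —
with as few as two records the sample estimator inflates dispersion.
RLC and VRC are set-level and default to 1 for a single record; SRC is
intra-record (cv of a record's own sampling intervals) and aggregates by
the median. All-zero value ranges give VRC = 1 (a perfectly stable, if
silent, sensor).

## Synthetic cohort generator

The generator emulates the *quality structure* of multimodal smartphone
data, not its physics: base signals are a low-frequency sinusoid plus a
bounded AR(1) walk with a per-channel DC offset (which gives the clean
record a comfortably positive SNR so noise injection has headroom).
Degradations are applied per record in a fixed order — noise, spike
anomalies, burst missingness — and each knob is validated by a
parameter-recovery property:

- **Missingness**: an exact number of interior points is deleted, mostly
  in geometric-length bursts (a minority of isolated drops, capped so
  surviving runs average ≥ 8 points and the modal interval stays the base
  interval). First and last samples are kept; surviving timestamps are
  untouched. Computed MDR lands within ±0.01 of the target.
- **Noise**: targets above ≈ −1.5 dB use white Gaussian noise with σ
  bisected on the realized SNR of the actual record. Lower targets use a
  Gaussian scale mixture — noise amplitude follows a smooth lognormal
  envelope `exp(a·u)` driven by a slow AR(1) process (correlation length
  ~30 samples) — with the exponent `a` bisected instead. The amplitude
  continuum deliberately avoids creating a discrete cluster of outlier
  points that the anomaly detector would (correctly) flag. Because spikes
  and heavy deletion shift the final record's SNR, the per-record noise
  target is corrected by up to three fixed-seed re-runs of the
  degradation chain; realized cohort medians land within a few tenths of
  a dB of target.
- **Anomalies**: a Bernoulli subset of points is replaced by spikes of
  1–2× `spike_scale` standard deviations (magnitudes jittered so dense
  anomaly sets do not form a tight self-masking cluster), random sign per
  channel, with the ground-truth mask returned so detector recall is
  testable.
- **Dispersion**: record lengths and per-record amplitude scales are
  lognormal with configurable cv; timestamps get Gaussian jitter;
  degenerate (0/1-point) records and channel dropout occur at configured
  rates.

The device presets encode the published per-device medians for MDR, SNR
and APD per sensor (accelerometer, gyroscope, GPS), e.g. GPS missingness
0.99 (iOS-like) vs 0.42 (Android-like) and gyroscope SNR −13.2 vs
−7.63 dB. The consistency knobs (jitter cv, length cv, range cv,
degenerate and channel-drop rates) have no published raw-scale medians —
the printed consistency values are cohort-normalized — so they are free
choices with the iOS-more-consistent direction: Android 0.03/0.35/0.40
and 5%/3% versus iOS 0.01/0.15/0.20 and 2%/1%. Mean record length is
1000 points (GPS: 5000, so that 99% missingness still leaves the ≥ 20
points anomaly scoring needs); 20 records per participant by default.

What the generator does **not** emulate: physical motion or geodesy,
diurnal/behavioural rhythms, device-model heterogeneity within a
platform, or correlated quality across sensors of one participant beyond
what the shared profile induces. Passing tests therefore demonstrate that
the *pipeline* recovers and separates controlled quality structure — not
that real Android/iOS data must separate to the same degree.

Known couplings, documented rather than hidden: very heavy-tailed noise
(≤ −7 dB) partially hides injected spikes from the detector (recall drops
toward ~0.5 and measured APD under-shoots its target), and extreme GPS
missingness leaves so few points that per-record APD is frequently zero.
Both mirror genuine identifiability limits of the definitions, and the
device contrast the audit relies on survives them.

## Statistics

Device contrasts use the two-sided Mann–Whitney U with tie-corrected
normal approximation; medians and IQRs are reported per group. Covariate
associations use Kruskal–Wallis per metric with the ε² = H/(n−1) effect
size, Dunn's rank-based pairwise z tests (implemented directly: pooled
ranks, tie-corrected variance) and Benjamini–Hochberg correction — across
all pairwise tests within a metric's family, and across metrics for the
omnibus tests. Levels with fewer than two observations are dropped with a
warning.

## Device-type audit

Features are one row per participant: 8 metrics × sensors (24 combined,
8 per-sensor), labels android = 0 / ios = 1; rows with any missing
feature are dropped with a log message. The classifier is a random
forest tuned by shuffled stratified 12-fold CV on a stratified 70/30
training split over trees {100, 300, 500} × depth {3, 5, 10, ∞} × min
leaf {1, 5, 10}, scored by the mean of accuracy (at the Youden-J
threshold), AU-ROC and AU-PRC on pooled out-of-fold predictions. Two
operating thresholds are kept: Youden-J (accuracy, sensitivity,
specificity) and max-F (precision, recall). Confidence intervals are
percentile 95% bands over repeated re-shuffled CV on the training split
(default 100 repeats; 1000 matches the reference protocol). A fold
missing a class triggers a logged reshuffle with an incremented seed.

The permutation null shuffles labels over the full design and re-runs
split–fit–evaluate per shuffle with the already-tuned hyperparameters;
re-tuning the full grid per shuffle is available (`retune=True`) but
changes the null negligibly while costing two orders of magnitude more.
The empirical p uses the add-one rule, so the smallest attainable p with
n permutations is 1/(n+1).

SHAP attributions are computed by an exact path-dependent TreeSHAP
implementation (iterative, numba-compiled), attributing the iOS-class
probability; additivity to the model output holds to ~1e−15 and is
asserted at 1e−6. IS is the per-feature mean |attribution| normalized by
its maximum; IL is the per-observation attribution divided by the global
max |attribution|, preserving sign (negative → Android-oriented). The
normalizer is chosen precisely so IL spans [−1, 1].

## Problem sizes used in the test suite

The end-to-end checks run at desk scale, chosen as the smallest sizes at
which every property is comfortably away from its decision boundary: the
generator-recovery grids use 30 participants × 20 records × 1000 points;
the separability audit uses 100 participants per device × 10 gyroscope
records with a 200-shuffle null; the SHAP direction check uses 50
participants per device × 10 GPS records. The `dqm demo` command runs the
same pipeline at similar sizes in a few minutes on one CPU.
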