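# Methods

`cyclecast` implements an hourly seizure-risk forecaster driven by
circadian and multiday cycles in epileptiform activity (EA), of the kind
recorded by chronically implanted sub-scalp EEG systems. Raw recordings
from such devices are not publicly available, so the package pairs the
analysis pipeline with a synthetic-data generator that reproduces the
statistical structure the pipeline assumes. This note documents the model,
its parameters and defaults, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Input model

The pipeline consumes two series:

* **Hourly event counts** `EventRateSeries`: machine-detected EA events
  aggregated per clock hour (12 a.m., 1 a.m., ...), on a contiguous hourly
  grid with an explicit missing-data mask. Timestamps are timezone-naive
  local clock time; daylight-saving shifts are out of scope.
* **Seizure onsets** `SeizureTimes`: strictly increasing timestamps of
  electrographically confirmed seizures. A seizure occurring at any minute
  of an hour labels that whole clock hour as a seizure hour.

Hours with partial data loss are treated as fully missing.

## Cycle detection in event rates

Event counts are z-standardized over non-missing hours (population SD) and
missing hours are imputed with 0, the post-standardization mean, so the
spectral stages always see a regular grid and gaps contribute no power.

A Morlet continuous wavelet transform (central frequency omega_0 = 6,
FFT implementation with zero padding to the next power of two) is
evaluated at a fixed grid of candidate periods: every 1.2 h from 2.4 to
31.2 h, every 2.4 h from 33.6 to 48 h, every 4.8 h from 52.8 to 96 h and
every 12 h from 120 h upward, truncated at one quarter of the recording
duration so that at least four repetitions of every candidate fit the
data. The **global wavelet spectrum** is the time average of squared
wavelet amplitude per scale, excluding hours inside the cone of influence
(edge distance < sqrt(2) x scale, the Morlet e-folding time).

Significance per scale uses the time-averaged chi-square test: the
background spectrum is an AR(1) red-noise spectrum with lag-1
autocorrelation estimated from the standardized series (a white background
is available via `RunConfig.background`), scaled by the chi-square
quantile at the configured confidence (default 99%) with
`nu = 2 * sqrt(1 + (n_avg / (2.32 * scale))^2)` degrees of freedom.
Significant cycles are strict local maxima of the global spectrum above
that level; plateaus produce no peak and grid endpoints cannot be peaks.
A calibration caveat: the test is *per scale*, so scanning a ~40-period
grid still produces an occasional spurious peak familywise (measured
per-scale exceedance on white noise is 1-2.5% against the nominal 1%;
roughly a fifth of pure-noise runs show one spurious peak somewhere).
Downstream feature selection tolerates this because spurious cycles are
almost never seizure-phase-locked.

Overlapping detections are pruned by a **sparsity rule**: greedily by
descending power, a period is kept only if its frequency lies outside the
band-pass pass band (+/-33% of the cycle frequency, the `bandpass_fraction`)
of every already-kept period.

Each kept cycle's instantaneous phase is the angle of the analytic signal
(Hilbert transform) of the series filtered by a zero-phase
(forward-backward) 2nd-order Butterworth band-pass at +/-33% of the cycle
frequency. "Zero-phase" matters: the filter introduces no lag, at the
price of being acausal — see Leakage below. Forward-backward filtering
uses even-reflection padding of a few cycle periods; the default (odd,
very short) padding distorts boundary phase badly for multiday bands.
Cycles whose pass band would reach the Nyquist frequency (periods below
~2.7 h at hourly sampling) cannot be phase-extracted and are skipped with
a warning. During imputed gaps the filtered amplitude envelope rings down
toward zero while the phase remains formally defined; those hours are
masked for forecasting.

## Cycles in seizure times

Seizure-time cycles are fixed sinusoids of candidate period (the same
period grid), with phase measured from the series start
(`phase(t) = 2 pi ((t - anchor)/period mod 1)`). Since only sin/cos of
phase enter the features and the downstream models are invariant to a
fixed rotation of a feature pair, the anchor convention is free; the
series start is used.

Two circular statistics decide locking:

* **Synchronization index (SI)** — the modulus of the mean unit phasor of
  the seizure phases; 0 for a uniform sample, 1 for perfect alignment.
* **Hodges-Ajne omnibus test** — with m the minimum number of phases in
  any closed half-circle, the exact small-sample p-value
  `p = 2^(1-n) (n - 2m) C(n, m)` for n <= 50 and the standard
  large-sample approximation beyond; p is capped at 1, and a maximally
  spread sample (m = n/2) yields p = 1. The half-circle scan is exact
  (boundaries at midpoints between data points and antipodes, with angles
  snapped to a 1e-12 grid so that exact antipodal configurations count
  correctly). Below n = 5 the test has essentially no power and returns
  p = 1 with a warning.

A candidate period becomes a seizure cycle when the omnibus test rejects
uniformity (p < 0.05) **and** SI >= 0.4; retained periods are greedily
pruned by descending SI so no kept period lies within the +/-33% frequency
band of a stronger one. Note that seizures locked simultaneously to two
cycles (e.g. 18 and 29 days) genuinely concentrate on sum/difference
frequencies as well, so the scan typically retains a few such combination
periods alongside the injected ones; they carry real joint-phase
information and are kept by design.

Event-rate cycles are used as forecast features only if seizures are
phase-locked to them (omnibus p < 0.05 on the Hilbert phases at seizure
hours). The SI >= 0.4 criterion applies to seizure-time cycles only.

## Forecasting model

Each kept cycle contributes two features per clock hour: sin(phase) and
cos(phase). Rows where an event-rate cycle's phase is undefined (device
gap) are masked; seizure-cycle features, being fixed sinusoids, are
defined everywhere including gaps.

The per-hour label is "a seizure onset falls within this clock hour".
Seizure hours are oversampled (duplicated uniformly at random with
replacement, seeded) until the classes are equal. A random-forest
*regressor* (bagging, 80 trees, minimum leaf size 15, scikit-learn
defaults otherwise) is fit on the balanced {0,1} targets; a logistic
regression (scikit-learn defaults) is then fit on the original-scale
features augmented with the forest output, and its positive-class
probability is the hourly **likelihood**. Because of the balancing, the
likelihood is calibrated to the balanced prior: it is deliberately much
larger than the raw hourly seizure probability and should be read as a
relative risk score, not a probability.

## Risk stratification

Two thresholds split likelihoods into low/medium/high states
(closed lower bounds: high iff likelihood >= high threshold). They are
chosen by exhaustive search over all achievable partitions (candidate
thresholds are midpoints between consecutive distinct likelihood values):
among pairs satisfying

* C1: time in low > time in medium > time in high, and
* C2: seizures in high > seizures in medium > seizures in low,

the pair maximizing (low-risk time fraction) x (number of seizure events
in high risk) is returned; if no pair satisfies both, the global maximizer
of that product is used. Ties break toward larger low-risk time, then the
lower high threshold. Seizures are counted as events by the state of
their containing hour. The search is rank-based, hence invariant to
monotone transforms of the likelihood, and is exact (an O(K log K)
interval argument over the cumulative hour/seizure counts replaces the
naive O(K^2) pair scan; tests verify equality with brute force).

The likelihoods used for threshold optimization are the ensemble's
predictions on the training window with the forest's out-of-bag
predictions substituted for its in-sample output. In-sample forest
predictions separate the training seizure hours almost perfectly, which
drives the optimizer toward thresholds that look excellent in-sample but
under-capture future seizures; the out-of-bag substitution is the
standard unbiased estimate of how the forest scores unseen hours and
yields thresholds that transfer to the test period.

## Pseudo-prospective protocol

Cycle detection (event-rate scan, seizure-time scan, locking filter) is
performed **once on the entire recording**, reproducing the published
protocol. The model and thresholds are first fit on a 14-day warm-start
window (`initial_train_days`); forecasts are then emitted for every later
clock hour, and after each observed test seizure the model and thresholds
are refit on all past data (one retraining per seizure event). During
masked (gap) hours the forecast carries the most recent defined
likelihood forward, flagged as carried.

### Leakage

Deriving cycles from the full recording is retrospective: the warm-start
model already knows which periods will be significant and the exact
filtered phases, which depend (weakly, through the zero-phase filter and
the global standardization) on future samples. The emitted provenance
flags this prominently. `RunConfig.causal_cycles = True` provides a
selection-causal variant in which cycle *selection* uses only the
warm-start window; the band-pass phases still come from full-series
zero-phase filtering, which is inherently acausal, so even this mode is
not strictly prospective. The headline benchmark reproduces the published
(leaky) protocol.

## Evaluation

Over the test window (all hours after the warm start):

* **AUC** — rank-based probability that a random seizure hour outranks a
  random non-seizure hour (ties count one half); carried (gap) hours are
  excluded because their likelihood is not a model output.
* **Time fractions** per risk state over all test hours, including
  carried hours under their carried labels.
* **Seizure fractions/counts** per state of the containing hour.
* **Median high-risk lead time** — for each seizure in a high-risk hour,
  the hours since the current uninterrupted high-risk run began; the
  median is reported, or absent when no seizure falls in a high-risk hour.

## Synthetic benchmark

`participant1_benchmark()` emulates the structure of the case-study
recording: 183 days of hourly counts, baseline 12 events/h, three
rate cycles — 24 h, 432 h (18 d) and 696 h (29 d), amplitude 4 events/h
each — with the two multiday cycles also seizure-locked (von Mises
concentration kappa = 5, preferred phase 0), 134 seizure onsets placed at
distinct hours with probability proportional to
`prod exp(kappa cos(theta_cycle - preferred_phase))`, counts drawn
Poisson, and a 12-day device-removal gap from day 100. Amplitudes are the
package's own choice (the real amplitude/noise ratio is unpublished):
4 events/h is ~1.2 Poisson SDs at baseline 12, the summed excursion never
exceeds the baseline (the rate stays non-negative without persistent
clipping), and all three cycles are reliably detected at 99% wavelet
confidence over the available repetitions. Phase 0 at the recording start
guarantees seizures in the warm-start window, as in the case study.

What the generator deliberately omits: raw EEG, detector false-positive
bursts, diary under-reporting, medication effects, seizure clustering
beyond the one-per-hour limit, cycle phase drift and amplitude
non-stationarity. Passing the benchmark therefore shows that the pipeline
correctly recovers and exploits the cyclic structure it models — not that
real recordings are this forecastable; the synthetic cycles are cleaner
than physiological ones.

Benchmark problem sizes were chosen to keep a full 10-seed evaluation at
desk scale: each seed runs ~4,400 forecast hours with ~110 retrainings of
the 80-tree forest on up to ~14 feature columns.

A note on the resulting operating point: because the low-risk time
fraction depends only on the medium threshold and the high-risk seizure
count only on the high threshold, the product objective always prefers
the tightest high region the C1/C2 orderings allow. On the benchmark's
clean synthetic likelihoods the optimizer therefore typically flags only
~10% of hours as high risk, capturing ~80% of test seizures (median AUC
~0.92 over seeds); at a fixed budget of 26% of hours flagged high, the
same likelihoods capture >90% of seizures. Forecasters evaluated on
noisier real recordings tend to land on wider, less specific high
regions for the same criteria.

## Numerical choices and degenerate inputs

* Morlet omega_0 = 6; Fourier factor 4 pi / (omega_0 + sqrt(2 + omega_0^2)).
* AR(1) coefficient clipped to [0, 0.999]; constant series yield alpha = 0.
* Wavelet scales with no cone-free hours fall back to the full time
  average (cannot occur for periods <= duration/4).
* All phases are wrapped to [0, 2 pi).
* Constant training features train with a warning and predict ~0.5 (the
  balanced base rate); constant likelihoods yield degenerate thresholds
  straddling the single value, with a warning.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a single master seed fans out to per-stage
  seeds, and repeated runs are bit-identical.

## Known limitations

* The headline protocol is retrospective in its cycle derivation (see
  Leakage); reported performance overstates what a strictly causal
  deployment would achieve.
* The Hodges-Ajne large-sample approximation (n > 50) is accurate to a
  few percent in p near the rejection region, which is ample for a 0.05
  gate but not for reporting extreme p-values.
* The wavelet significance test controls the per-scale, not familywise,
  error rate.
* Risk-threshold optimization assumes the training likelihood
  distribution transfers to the near future; regime changes (e.g.
  medication changes) would break this silently.
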