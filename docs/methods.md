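# Methods

## Problem

Consumer wearables deliver continuous heart-rate (beat-to-beat N-N
intervals, NNI) and step-count streams whose accuracy is routinely
questioned. `wearsim` asks how much that matters for *prediction models
built on top of such streams*: it trains a random-forest regressor to
predict a per-participant cardiac competence index (CCI) from features of
one day of free-living data, then degrades the raw series in controlled
ways and tracks how cross-validated prediction error (RMSE) responds, from
the unperturbed condition to degradation levels far beyond what real
devices exhibit.

Because suitable real cohorts require a restricted download, the package
ships a synthetic-data generator whose participants carry *known* latent
parameters. Every stage of the pipeline is therefore testable against
ground truth, and the degradation experiment runs end-to-end with no
external data. An ingestion adapter for MMASH-style per-participant CSV
directories (`RR.csv`, `Actigraph.csv`, `Activity.csv`, `user.csv`) is
provided so the same pipeline can be pointed at real exports.

## Target: the cardiac competence index

For each participant,

* **baseline HR** = minimum of a rolling 2-minute mean of per-minute HR
  over diary periods of rest (lying down or sitting),
* **peak HR** = maximum of the same rolling mean over heavy-exercise
  periods,
* **predicted HR** = 220 − age,
* **CCI** = (peak − baseline) / (predicted − baseline).

Rolling windows must lie fully inside a single diary interval; windows
straddling two activities are discarded (the membership rule is otherwise
under-determined). CCI is computed once from unperturbed data and held
fixed across all perturbation conditions — the target must not move when
the inputs degrade. (A target recomputed from perturbed data would measure
target drift, not model robustness.)

## Synthetic cohort

The generator draws, per participant: age (uniform integers 20–30),
baseline HR (Normal(62, 4) bpm, clipped to [45, 80]), and a latent CCI
(uniform on [0.55, 1.05]); peak HR is derived as
`baseline + CCI·((220−age)−baseline)`, so the latent truth is always
physically realizable. Drawing baseline/peak rather than CCI directly
guarantees a valid NNI stream.

The activity diary partitions the record into a sleep block (28–34% of the
record) followed by a fixed waking template: two light, two medium and two
heavy-exercise bouts with bounded lengths (heavy 20–40 min each at 24 h,
scaling proportionally on shorter records with a 5-minute floor), with
rest blocks absorbing the remainder — roughly half the day, as in
free-living actigraphy where sitting dominates. Every diary contains at
least one sleep, rest and heavy-exercise block; records shorter than 2 h
are rejected.

Instantaneous HR follows a plateau per diary category — sleep and rest at
baseline HR, light at baseline + 25% of the reserve, medium + 60%, heavy
exercise at peak HR — with a 60-s linear ramp at each interval start.
Sleep shares the rest plateau so that the minimum rest-window rolling mean
identifies the baseline exactly at zero jitter; transitions always ramp
*toward* the new plateau from within the new interval, so interior windows
of rest (heavy) intervals attain the plateau minimum (maximum). Beat
generation is sequential: each beat's HR is the profile value plus i.i.d.
Gaussian jitter (default SD 1 bpm, clipped at 20 bpm from below so NNIs
stay positive and bounded), its NNI is 60/HR seconds, and the next beat
starts one NNI later. Steps are Poisson counts per 1-s epoch with
per-category rates (sleep 0, rest 3, light 40, medium 70, heavy 130
steps/min).

What this emulates — and what it does not: the generator reproduces the
*structure* that the pipeline depends on (diary-locked HR plateaus, a
recoverable latent CCI, silent-sleep step streams) but not physiological
HRV dynamics (respiratory sinus arrhythmia, circadian drift, sleep
staging) or device artifacts. Passing tests therefore demonstrate that the
pipeline measures what it claims on data with known structure; they do not
certify feature values on real recordings.

Defaults: 21 participants, 24-h records, 1-s step epochs. Determinism is
bit-exact per (seed, config).

## Preprocessing

The first 5 minutes of every stream are dropped (device placement), with
the origin shifted and the diary re-clipped. Per-minute step count (PMSC)
sums step epochs over half-open minutes [60m, 60(m+1)); sleep minutes
(midpoint rule) are deleted, not zero-filled. Per-minute HR is the plain
mean of per-beat 60/NNI over each minute (beat-mean, not duration-
weighted), floored at 35 bpm — the lowest plausible value; minutes without
beats are marked absent rather than interpolated, since the missingness
perturbation supplies its own fill rule.

## Features (catalog version 1.0, 102 features)

* NNI time domain: median, mean, SD, RMSSD, RMS of the values, range,
  pNN50. "Root mean square" of an NNI series is ambiguous; RMSSD — the
  standard short-term HRV statistic — is the primary reading, and the RMS
  of the raw values is additionally emitted under `nni_rms`.
* HR time domain: max, min, mean, SD of the per-minute series.
* Frequency domain: the NNI tachogram is linearly interpolated to a
  uniform 4-Hz grid and its spectrum estimated by Welch's method (segment
  length min(n, 4096) samples ≈ 17 min, covering more than two VLF
  periods); band powers integrate the PSD over VLF (0.003–0.04 Hz), LF
  (0.04–0.15 Hz) and HF (0.15–0.40 Hz), plus LF/HF, LF/(LF+HF) and
  HF/(LF+HF). Series shorter than 5 minutes are rejected.
* Poincaré: SD1² = ½·var(ΔNNI), SD2² = 2·var(NNI) − ½·var(ΔNNI), and
  SD1/SD2. SD2 = 0 (a degenerate plot) rejects the ratio.
* PMSC summaries: max, median, 25th/75th percentile.
* A generic catalog applied to each of the three series (HR, NNI, PMSC):
  autocorrelations at lags 1–10, partial autocorrelations at lags 1–5,
  lag-1 autocorrelation of the differenced series, quantiles at
  {1, 5, 25, 50, 75, 95, 99}%, and the proportion of lag-1 jumps
  exceeding k·SD for k ∈ {1, 2, 3} (26 features per series). This is a
  fixed, versioned stand-in for the sprawling catalogs of general-purpose
  time-series feature packages; matching any particular external catalog
  is a non-goal.

Conventions used throughout: population (ddof = 0) variance; quantiles by
linear interpolation between order statistics; correlation features of a
constant series are 0 by convention.

## Perturbations

Four families, each with a 75-level grid:

* **Missingness** (5% → 93.8% in 1.2% steps): segments of 1–5 minutes are
  drawn (length uniform, start uniform over still-free positions;
  overlapping draws are re-placed) until the removed duration reaches the
  target fraction; the last segment may overshoot by less than its own
  length. One mask over the record's minute timeline is shared by all
  three series. Inside removed segments HR = 35 bpm, NNI = 500 ms,
  PMSC = 0 (the HR/NNI replacement values are part of the protocol; PMSC
  has no stated replacement and 0 is the natural silent value).
* **Flicker noise** (2% → 150% in 2% steps): 1/f noise, generated by
  shaping Gaussian Fourier coefficients with f^(−1/2) and inverse-
  transforming, rescaled to SD = level × mean(series) — SD being the
  standard reading of a noise "amount" — and added; HR and NNI are then
  rectified (absolute value, floor at 1) and PMSC floored at 0. The three
  series of a participant receive independent realizations.
* **Bias** (2% → 150%): a deterministic shift of +level × mean(series) —
  an additive offset (parallel displacement), not multiplicative scaling.
* **Combined**: noise, then bias, then missingness at index-paired levels
  (grid index i ↦ 2i% noise and bias, (5 + 1.2(i−1))% missingness);
  missingness last, so removed segments contain exactly the replacement
  values.

The 0% noise/bias level is the unperturbed condition, which is evaluated
separately; the grids hold the 75 non-trivial levels. Per-condition seeds
derive from (master seed, family, level, participant) so conditions are
reproducible and mutually independent.

## Experiment

Per family, 76 conditions (unperturbed + 75 levels). Features are
re-extracted from the perturbed series of every condition; CCI targets and
the feature preselection are frozen from the unperturbed data. Preselection
first drops features that never vary across the entire condition stack
(uninformative by construction), then keeps features whose Pearson
correlation with CCI on the unperturbed matrix has two-sided P ≤ 0.10 — no
multiple-testing correction, by design. The frozen set is reused for every
condition.

Each condition is scored by repeated 3-fold cross-validation (default 25
repetitions): per repetition, a fresh shuffled fold partition and forest
seed; the random forest (scikit-learn defaults, echoed verbatim into run
metadata) is fit on the training folds and all held-out predictions are
pooled into a single RMSE. The condition's score is the mean of the
repetition RMSEs with SE = SD/√reps. The reference is the baseline RMSE of
the mean predictor — the population SD of the targets (the sample-SD
alternative differs by <3% at n = 21). The breakdown level of a family is
the smallest grid level at which the 3-point-smoothed RMSE curve reaches
the baseline and stays there; a single touch does not count.

## Problem sizes

Unit and property tests run on records of 2.5–3 h and cohorts of 2–6; the
qualitative degradation experiment (acceptance tests and
`scripts/acceptance.py`) uses 21 participants, 6-h records, 10 CV
repetitions and every 5th grid level, taken from the top so the highest
level of each family (93.8% missing, 150% noise/bias) is always present.
These scaled sizes are the package's standard desk-scale configuration;
`analysis/03_run_degradation_experiment.py --stride 1 --reps 25 --hours 24`
runs the full-resolution study.

## Known limitations and observed behaviour

* With a strong latent signal, extreme-value features (HR maximum, NNI low
  quantiles) are near-noise-free proxies of peak HR. Because missingness
  *replaces* segments and leaves retained minutes exact, these features
  stay informative as long as any exercise minute survives — probability
  ≈ 1 − (1 − r)^k at retained fraction r and k exercise minutes. The
  synthetic degradation curve for missingness therefore rises toward, but
  does not fully reach, the baseline at the top of the grid, whereas a
  model with a slim unperturbed margin (as is typical on small real
  cohorts) reaches it much earlier.
* The bias family leaves shift-invariant features (autocorrelations, SDs,
  pNN50, ranges) untouched; the residual slow RMSE rise comes from
  location-dependent selected features, whose per-participant shift
  λ·mean(series) mildly reorders participants. Bias never drives the model
  to the baseline at any level — the qualitative finding this family is
  designed to show.
* The generator's jitter is white on instantaneous HR, so its
  frequency-domain features carry no structured LF/HF physiology; they are
  exercised for correctness, not realism.
* Preselection with n = 21 at P ≤ 0.10 admits ~10% of pure-noise features
  (verified by simulation); the frozen set is diagnostic of the synthetic
  cohort, not of any real population.
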