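# Methods

## Screening model

An S-ICD senses from one of three electrode vectors; a T wave large
relative to its preceding R wave risks being double-counted as a beat
(T-wave oversensing), which can trigger an inappropriate shock. The
screening quantity is therefore the per-vector T:R amplitude ratio,
and the package evaluates it two ways over a long recording cut into
10-s segments:

* **Standard pass probability** — the fraction of segment indices at
  which at least one present vector has T:R strictly below 1:3. This
  is the probability of passing a one-off screening performed at a
  uniformly random time in the monitoring period; the 24-h denominator
  is 8640 segments.
* **Prolonged screening** — at each cutoff r ∈ {1/3, 1/2, 2/3, 3/4, 1},
  a vector *fails* if its T:R is unfavourable (≥ r; the boundary is
  unfavourable, favourability is strict `tr < r`) for at least 20
  consecutive seconds — ⌈20 s / 10 s⌉ = 2 consecutive segments at the
  defaults. 20 s stands in for the device's detect–charge–redetect–
  shock sequence; isolated 10-s ("silent") unfavourable episodes pass.
  Both the cutoffs and the duration are parameters. A patient passes a
  cutoff iff at least one non-missing vector passes it; patients with
  missing vectors are judged on the vectors they have.

Pass decisions are monotone in the cutoff by construction (favourable
sets grow with r), at the vector, patient and cohort levels.

### Missing estimates inside a series

A per-segment estimate can be missing (e.g. the beat detector found
fewer than 3 beats). Missing segments *break* unfavourable runs — they
are treated as favourable for run-building — so estimator dropouts can
never fabricate a 20-s failure; the number of missing segments is
reported on every vector result so the conservatism is auditable. In
the standard pass probability, a missing value simply does not count
as favourable. Whole-missing channels are first-class (flagged, never
imputed) and excluded from denominators, which is why per-vector
cohort tables can have a smaller N than the patient-level tables.

## T:R estimation

**Waveform oracle.** R peaks are detected on a squared-derivative
moving-average envelope (120 ms window, peaks ≥ 25% of the envelope
maximum, 250 ms refractory distance), refined to the nearest absolute
maximum of the signal within ±60 ms. For each beat, the T peak is the
absolute-maximum deflection in the window (R + 120 ms, R + 0.6·RR).
Amplitudes are measured relative to the isoelectric level estimated by
the segment median: baseline correction re-centers the signal to zero
mean, which shifts the isoelectric line by the mean of the beat
waveform (~0.08 mV for the default morphology), and peak-from-zero
measurement would bias T:R low by ~0.05. The estimate is the median
over beats of |T|/|R|, robust to single-beat misdetections and
invariant to uniform amplitude scaling. Fewer than 3 detected beats
yields a reason-coded missing value.

**PSR-image regressor.** Each preprocessed segment is embedded as
delay pairs (x[t], x[t+τ]) with τ = 10 samples (20 ms at 500 Hz),
min–max normalized to [0,1], and binned into a 32×32 occupancy
histogram (right-closed final bin; row = x[t] bin) scaled by its
maximum count. The regressor mapping image → T:R is a gradient-boosted
tree ensemble (`HistGradientBoostingRegressor`, 200 boosting rounds)
over the 1024 flattened pixels. A tree ensemble was chosen over a
neural regressor after a direct comparison: on recording-grouped
held-out data the boosted trees reach out-of-fold MAE ≈ 0.005 while a
one-hidden-layer MLP on the same features failed to generalize across
recordings (MAE ≈ 0.22); the trees are also deterministic for a fixed
seed and train in about a minute on one CPU. The estimation target and
its evaluation procedure, not a particular architecture, are the
substance here.

**Cross-validation.** Tenfold, with folds assigned at the recording
level (GroupKFold) so segments of one recording never straddle the
train/validation split. The report pools out-of-fold predictions for
MSE, RMSE = √MSE and MAE, and also carries per-fold metrics plus their
fold-averaged variants, since pooled and fold-averaged RMSE differ in
general and published accuracy figures do not always say which
aggregation was used.

## Preprocessing

Applied per 10-s segment, in order; every stage is zero-phase so R and
T amplitudes/timings stay comparable to the clean signal:

1. **Baseline removal** — two-stage median filter (200 ms then 600 ms
   windows) estimates the drift, which is subtracted; the output is
   re-centered to exactly zero mean. Attenuates 0.3 Hz wander by
   >20 dB while changing QRS excursions <5%.
2. **50 Hz band-stop** — second-order IIR notch (Q = 30) run
   forward–backward: ≥40 dB at 50 Hz, <1 dB at 10 Hz. Mains-frequency
   tracking is unnecessary for synthetic data with a fixed 50 Hz tone.
3. **40 Hz low-pass** — 4th-order Butterworth, forward–backward:
   ≥40 dB at 100 Hz, <1 dB at 5 Hz, no measurable R-peak shift.

Cutoffs, notch Q and median windows are exposed in `FilterConfig`.

## Synthetic data generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with the R
peak at 40% of the cycle; amplitudes are in mV (R = 1.0 by default)
and the T amplitude is set per segment to `tr × R`, so the ground-truth
T:R of every segment is exact by construction and synthesis rejects
templates whose component overlap would perturb the R or T peak by
more than 1% of R. Heart rate is fixed per recording (no HRV; rate
effects are out of scope). The per-segment T:R trajectory is a
circadian sinusoid (default amplitude 0.08, period 24 h) around a
subgroup baseline plus i.i.d. Gaussian jitter (sd 0.03), clamped to
(0, 2]. Default subgroup baselines — ACHD 0.45, HCM 0.38, HF 0.42,
normal hearts 0.22, prior-inappropriate-shock 0.80 — order the
subgroups plausibly (normal hearts favourable, prior-TWO-shock
patients near the top thresholds) but are free simulator parameters,
not calibrated clinical claims. Noise is additive and applied after
the truth is fixed: sinusoidal baseline wander (0.15 mV at 0.3 Hz),
50 Hz mains (0.05 mV) and white noise (0.02 mV sd).

What the generator does **not** emulate: morphological variety between
beats, arrhythmia, posture changes, electrode artifacts, heart-rate
variability, or realistic subgroup-specific ECG morphology. Passing
tests on this data therefore demonstrates that the pipeline's
measurement and decision logic is correct under controlled conditions,
not that the estimator achieves any particular accuracy on clinical
recordings.

## Exact cohort statistics

Subgroup-by-outcome tables from cohorts of a few dozen patients have
cells far too small for chi-square asymptotics, so independence is
tested with Fisher's exact test generalized to r×c: conditioning on
the margins, the null is multivariate hypergeometric,
P(T) = (∏ᵢRᵢ! ∏ⱼCⱼ!)/(N! ∏ᵢⱼnᵢⱼ!), and the two-sided p-value sums
P(T) over every margin-compatible table with P(T) ≤ P(observed). The
engine enumerates tables by recursive cell filling with margin
feasibility pruning, in log-factorial arithmetic; a relative tolerance
of 1e-7 on the probability comparison guards floating-point ties. The
enumerated probabilities sum to 1 (tested to 1e-9), 2×2 results agree
with the closed-form hypergeometric sum to 1e-9, and the p-value is
invariant to row/column permutation. Tables whose enumeration bound
exceeds ~5×10⁷ candidates are refused rather than silently
approximated. Continuous outcomes across subgroups use the
Kruskal–Wallis rank-sum test (tie-corrected H, chi-square reference
with K−1 df); identical values in all groups return H = 0, p = 1.
Report tables render counts as `n/N (x%)` with two-significant-figure
percentages.

## Problem sizes and numerical choices

* Cross-validation experiment: 34 recordings × 20 segments × 3
  channels = 2040 labeled segments, per-segment targets uniform in
  [0.1, 0.9] (covering the whole screening-relevant band), default
  noise, tenfold grouped CV — about 2–3 minutes on one CPU.
* Cohort-level integration tests use 200 s – 20 min recordings; the
  generator's API defaults to the full 24-h duration (8640 segments,
  43.2 M samples per channel at 500 Hz).
* Segment grid: trailing partial windows are dropped, never padded,
  so probability denominators always count whole 10-s segments.
  0-based segment indexing; segment k covers [10k, 10k+10) s.
* Degenerate inputs: constant segments produce an all-zero baseline-
  corrected signal and a single-center-pixel PSR image (warned);
  constant regression labels warn; empty metric inputs raise.
* Runs never wrap across the recording boundary.

## Known limitations

* The consecutive-failure surrogate is a fixed time window; real
  devices apply morphology discrimination and decaying sensitivity
  thresholds that can rescue or doom borderline vectors.
* The regressor is trained and validated on the simulator's beat
  morphology; transfer to clinical ECG would require retraining on
  manually labeled segments.
* Kruskal–Wallis uses the chi-square approximation, standard at these
  group sizes; no multiplicity correction is applied across the five
  thresholds (none is applied in the screening literature this
  mirrors).
* 60 Hz mains is configurable but untested; vendor binary Holter
  formats and EDF are out of scope.
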