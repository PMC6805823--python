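# Methods

This package simulates, end to end, the construction and evaluation of an
acoustic rule-out score for stable coronary artery disease (CAD): heart-sound
recordings are segmented into systolic and diastolic periods, eight acoustic
features are combined into an acoustic score by linear discriminant analysis
(LDA), the acoustic score is fused with age, sex and hypertension by logistic
regression, the fused linear predictor is scaled onto a 0–99 integer
"CAD-score" anchored so that 90 % of diseased training patients exceed the
rule-out threshold of 20, and the resulting score is evaluated with the full
diagnostic-statistics toolbox (exact confidence intervals, likelihood ratios,
Bayesian post-test probabilities, ROC/AUC comparisons, risk reclassification
with the net reclassification index, and repeated cross-validation).

The clinical databases such a score is built on are not public, so the
package ships a synthetic-data generator whose defaults encode the study
conditions the analysis assumes. Everything downstream of the generator is
generic and consumes cohort tables (CSV) and mono WAV recordings, so it can
be pointed at real data with the same interfaces.

## The synthetic cohort

`CohortConfig` draws, per patient, a disease level from the mix 46.4 %
non-CAD / 44.2 % mild-CAD / 9.4 % significant-CAD, then covariates
conditional on that level: age N(58.3, 8.4²) years with level shifts
(−0.6, 0, +3.0); female fraction (0.562, 0.520, 0.400) per level (marginal
≈ 52.8 %); hypertension (0.545, 0.605, 0.660) (marginal ≈ 58.5 %); a
four-category symptom mix (typical / atypical / non-specific / none) whose
marginal is ≈ 22/27/29/22 % and which is shifted toward typical chest pain
in significant-CAD; BMI N(26.9, 4.2²); diabetes ≈ 5.3 % marginal. The
conditional shifts give the clinical covariates a realistic level of
discrimination on their own (covariates-only AUC ≈ 0.68–0.74 for
significant-CAD vs other), which matters because the fused score's
performance target is only modestly above that.

All draws flow from a single integer seed through `numpy` generator streams
keyed by (cohort seed, patient index, repeat), so cohorts and waveforms are
bit-identical under a fixed seed, and a "repeat" recording of the same
patient re-draws only measurement noise, never physiology.

## The phonocardiogram model

Each recording (default: a 30 s quality-control pre-test segment plus a
150 s main recording at 1000 Hz) contains, per beat:

- S1: a Gaussian-windowed ~35 Hz transient of 120 ms, unit nominal
  amplitude with 8 % beat-to-beat jitter;
- S2: the same at ~55 Hz, 100 ms, amplitude 0.8, placed one systolic span
  after S1 onset. The systolic span is 0.35 s − 0.0012 s·(HR − 60), a
  simple physiologic shortening with heart rate;
- a diastolic murmur: band-limited (200–450 Hz) Gaussian noise gated over
  early-to-mid diastole. Its RMS amplitude is
  `murmur_scale · amp[level] · exp(0.9 · z)` with per-level base amplitudes
  (0.013, 0.016, 0.022) and a patient-specific lognormal factor
  (z ~ N(0,1)); and
- white broadband noise of RMS 0.02.

Heart rate is N(65, 8²) bpm truncated to [45, 110]; RR intervals have a
coefficient of variation of 0.03, or 0.30 for the configured arrhythmic
fraction (default 1.1 %), which exercises the quality-control rejection
path. Sampling at 1000 Hz is sufficient for the 200–450 Hz murmur band.

The murmur model is a stand-in motivated by the physics of post-stenotic
turbulent coronary flow (weak, high-frequency, diastolic — when coronary
flow peaks); it is not a claim about any device's actual signal. The
per-level amplitudes and the lognormal spread were calibrated once so that
the fitted score reaches an AUC near 0.75 for significant-CAD versus the
rest under the default conditions — i.e. the acoustic channel carries a
weak, heavily overlapping signal, as the application demands — and are not
otherwise meaningful. What passing tests show is therefore that the
*pipeline* behaves correctly on signals with this structure; they say
nothing about how informative real heart sounds are.

## Segmentation

The segmenter is envelope-based: band-pass 25–150 Hz (4th-order zero-phase
Butterworth), Hilbert envelope, 25 ms centred moving-average smoothing.
Candidate transients come from peak picking (minimum spacing 150 ms, height
threshold between the median envelope and its 99.5th percentile); the heart
period is estimated from the envelope autocorrelation (0.4–1.6 s lag), with
a median-gap fallback when an irregular rhythm washes the autocorrelation
out. Peaks are then labelled S1/S2/noise by a duration-constrained Viterbi
decoding over two states: an S1→S2 transition must fall in the absolute
systolic window 0.20–0.45 s, S2→S1 (diastole) in 0.15–1.6 s, a skipped
sound costs a fixed penalty, and the pairing score rewards S1 being the
taller of the pair. Absolute (not period-relative) duration windows keep
the decoder honest at high heart rates, where diastole can be shorter than
systole, and in arrhythmia, where a period-anchored comb would bias the RR
series toward its mean.

Interval boundaries (S1 onset/offset, S2 onset/offset) are refined by
walking from each peak to the 10 % crossing of its height above the median
floor, clamped to 1.2 nominal transient durations, with a half-nominal-width
fallback when the envelope never drops (heavy noise). Each beat's four
intervals partition [S1 onset, next S1 onset) contiguously, so their
durations sum to the RR interval exactly by construction. Recordings with
fewer than five decodable beats raise a segmentation failure.

On default-noise synthetic recordings the decoder recovers essentially all
S1 onsets within ±20 ms down to 5 dB broadband SNR; the test suite asserts
the ≥ 95 %-within-20 ms contract at 10 dB.

Quality control (run on the pre-test segment) rejects recordings shorter
than 15 s (`too_short`), with fewer than 20 decodable beats or an envelope
peak-to-background ratio below 2 (`noisy_or_weak`), or with a robust RR
coefficient of variation above 0.2 (`arrhythmia`). The RR series is
cleaned of missed/extra-beat artifacts (intervals outside [0.5, 1.6] ×
median) before the CoV is computed, and the arrhythmia check runs before
the beat-count check because irregular rhythms also defeat the beat
decoder.

## Features and the acoustic score

Eight features per recording, each computed per beat inside the segmented
intervals and aggregated by the median across beats (the eighth is itself a
cross-beat statistic). All are amplitude-scale invariant:

| # | name | definition |
|---|------|------------|
| 1 | `dia_band_ratio` | log10 of diastolic 200–450 Hz band power over total diastolic power |
| 2 | `sys_band_ratio` | the same for systole |
| 3 | `dia_spectral_entropy` | normalised Shannon entropy of the diastolic periodogram |
| 4 | `dia_ar_pole_freq` | frequency of the dominant AR(4) (Yule–Walker) pole of diastole |
| 5 | `dia_sys_rms_ratio` | log10 diastolic / systolic RMS |
| 6 | `s1_s2_amp_ratio` | log10 S1 / S2 envelope peak ratio |
| 7 | `dia_hf_fraction` | diastolic > 250 Hz energy fraction |
| 8 | `dia_power_cv` | beat-to-beat coefficient of variation of diastolic band power |

Exact feature definitions of the commercial device are proprietary; this
bank covers the same signal properties (diastolic murmur energy, spectral
shape and stability) and is deliberately redundant — with the default
simulator only the diastolic energy features carry signal, and the LDA is
expected to learn that. Median aggregation over beats (rather than the
mean) is a robustness choice against occasional segmentation slips.

The acoustic score is a two-class Fisher discriminant with the pooled
within-class covariance shrunk toward its diagonal,
S∗ = (1−γ)S + γ·diag(S), γ = 0.1 by default. Shrinkage keeps the solve
well-posed under duplicated or near-collinear features; as γ → 0 the
projection is affine-invariant as Fisher LDA should be. The sign is
oriented so that higher scores mean more disease-like.

## Fusion, scaling and the threshold

Logistic regression (maximum likelihood, statsmodels, tolerance 1e-8) of
the significant-CAD indicator on (acoustic score, age in years, male = 1,
hypertension = 1). Constant predictors are dropped with a warning. If the
ML fit separates perfectly or its Hessian is singular, the model falls
back to an L2-penalised fit (penalty 1e-4, scikit-learn lbfgs) and flags
itself `penalized`.

The linear predictor is mapped affinely to the score scale: the slope
spreads the central 95 % (2.5th–97.5th percentile) of all training linear
predictors over [5, 75]; the offset then pins the 10th percentile
(linear-interpolation quantile) of the significant-CAD linear predictors
to exactly 20, so that 90 % of diseased training patients land above the
rule-out threshold before rounding. Scores are rounded half-up and clamped
to [0, 99]; the threshold is fixed at 20, with > 20 classified abnormal.
The span-to-[5, 75] slope rule is this package's own choice (only the
90 %-above-20 anchor is externally specified) — it makes the integer scale
use most of its range without saturating; both anchors are configurable.
On the default training cohort (n = 2000) the post-rounding fraction of
diseased patients above 20 stays within 88–92 %; at very small n the
10th-percentile anchor is quantised by the handful of cases and the
calibration contract is not meaningful (the calibrator refuses < 20 cases
by default).

## Pre-test probability and reclassification

PTP is a logistic model in age, sex and symptom class (Diamond–Forrester
form). The published updated-model coefficients are not bundled: the
defaults are a synthetic stand-in chosen to produce a guideline-like
distribution on the default cohort (mean PTP ≈ 0.38; ≈ 16 % low, ≈ 82 %
intermediate, ≈ 2 % high), with a separate coefficient per symptom
category including `non_specific` and `none`, so an externally sourced
model can be dropped in via configuration. All reclassification logic is
tested with toy coefficients and never depends on the defaults.

Bands: low < 15 %, high > 85 %, intermediate otherwise — both edges belong
to intermediate. The scheme moves intermediate patients with score ≤ 20 to
low; nobody moves up, low and high are untouched. Asymptomatic patients
(symptom `none`) are excluded from the reclassification analysis, which
concerns patients referred for testing because of symptoms. The binary NRI
is (up−down)/events + (down−up)/non-events with events = significant-CAD;
with a down-only scheme the up-terms vanish.

Disease levels: significant-CAD requires ≥ 50 % diameter stenosis on
invasive angiography; non-CAD requires a zero calcium score and no CT
stenosis; anything else with a positive finding is mild-CAD; no modality
data raises an "unclassifiable" error.

## Diagnostic statistics

- Confidence intervals for proportions are Clopper–Pearson exact
  (`statsmodels proportion_confint(method="beta")`), the method that
  reproduces published exact bounds such as 83.6–92.6 % for 188/212; the
  method is configurable (e.g. Wilson) per call.
- Likelihood ratios are PLR = sens/(1−spec), NLR = (1−sens)/spec, kept
  unrounded internally so the Bayes identities
  post(prev, PLR) = PPV and 1 − post(prev, NLR) = NPV hold to machine
  precision; boundary cases (spec = 0 or 1) are flagged, not fatal.
- AUC is the normalised Mann–Whitney statistic (ties half credit); its CI
  uses the Hanley–McNeil variance. Paired AUC comparison is DeLong's test
  via placement values (midranks); unpaired comparison is a z-test with
  Hanley–McNeil variances.
- The chi-square test is Pearson's without continuity correction
  (df = (R−1)(C−1)); the uncorrected form is what reproduces published
  reclassification p-values. t-tests are equal-variance, ANOVA is one-way,
  correlation is Pearson.
- Stratified performance applies the identical machinery per stratum and
  omits the AUC where a stratum lacks one class.
- Reporting precision convention: percentages to 1 decimal, likelihood
  ratios to 2, NRI to 3.

## Cross-validation

`repeated_cv` re-trains both the LDA and the logistic fusion inside every
training fold of a stratified k-fold split, repeated with seeds
seed + repeat; out-of-fold linear predictors are pooled per repeat before
the AUC (averaging per-fold AUCs is available via `pool_scores=False`;
pooling was chosen because fold-level AUCs are unstable at ~20 events per
fold). `folds = n` requests leave-one-out (plain, unstratified). A split
leaving a training fold without events is redrawn with a warning. The
headline quantity is the optimism: resubstitution AUC minus mean CV AUC.
Two small-sample caveats are deliberate test-design choices: pooled null
CV AUCs are biased slightly below 0.5 at small n (fold-specific intercepts
anti-correlate with held-out labels), so null behaviour is asserted at
n = 2000; and resubstitution AUCs of an 11-parameter refit are optimistic
even under the null, so the pipeline's null test examines the
cross-validated AUC.

## Problem sizes

The default study conditions are n = 2000 patients with full-length
(150 s) recordings; the test suite and the acceptance script use exactly
these conditions for the calibration and cross-validation checks, and
smaller cohorts or shorter recordings (noted per test) for contracts that
do not depend on the study scale. Cross-validation defaults to 50 × 10-fold
in the analysis drivers; the acceptance-level checks use 5–10 repeats,
which is ample to estimate the mean CV AUC to well under the tolerance
being asserted.

## Known limitations

- The acoustic generator has no respiratory modulation, no S3/S4, no
  valvular murmurs, no sensor artifacts; QC's `noisy_or_weak` path is
  exercised only by synthetic noise.
- The simulated significant-CAD murmur is a single diastolic band; the
  systolic features and S1/S2 amplitude ratio are therefore pure noise
  under the default generator (their test-retest reliability is near
  zero), which is intentional redundancy but means small-cohort LDAs can
  overfit them.
- PTP defaults are synthetic stand-ins, not the published coefficients.
- Disease-level coding implements the main three-level definitions only,
  not cohort-specific coding edge cases (e.g. screening-study follow-up
  rules).
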