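# Methods

This note documents the models, estimators and design choices behind
`erdvoice`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions that shape the results.

## 1. Stimulus model

**Melodies.** Five isochronous notes, pitches on the equal-tempered
semitone grid (A4 = 440 Hz, C4 = 0). The female tessitura spans G3–G4
(−5…+7 semitones re C4); the male tessitura is the same material
transposed −7 semitones (C3–C4). Adjacent intervals are capped at 10
semitones. Because song repertoire favors small steps, interval magnitudes
are drawn from a truncated geometric distribution on 0…10 (success
probability 0.35, giving a mean step ≈ 1.8 semitones); the sign is random
and steps leaving the tessitura are redrawn. Repetitions (step 0) are
allowed. The distributional choice is ours — only the 10-semitone cap and
the ranges are externally fixed.

**Triangle timbre.** Each note is a band-limited triangle: odd partials
k ∈ {1,3,5,7} with amplitudes 1/k² and alternating sign — four partials
with strictly decreasing level. Notes last exactly 0.750 s with linear
5 ms rise/fall ramps; the clip is peak-normalized. Synthesis is
deterministic, and its descriptors (measured with the package's own
estimators, §4) come out at ≈0.0002% jitter, ≈0.016% shimmer and <0.01
cent f0 SD — an order of magnitude under the 0.05% / 1 cent bounds the
timbre must satisfy. An alternative reading of "fundamental plus first
three harmonics" is partials 1–4; both satisfy the bounds, we use the
triangle's odd-partial series because the timbre is named a triangle wave
(`n_partials` is configurable).

**Vocal-like timbre.** A synthetic stand-in for sung recordings, not a
voice model: the same additive core driven cycle-by-cycle with
(i) i.i.d. Gaussian period jitter, (ii) i.i.d. Gaussian cycle-amplitude
shimmer, and (iii) an Ornstein–Uhlenbeck drift of log-f0 (correlation
time 20 cycles). Defaults reproduce the measured descriptors of sung
stimuli in this paradigm: 0.29% jitter, 1.35% shimmer, 8.5 cents f0 SD,
0.738 s median note. Because the *measured* local jitter is
E|T_i−T_{i−1}|/T̄, the generator sets the per-cycle SD to
`target·√π/2` so the estimator recovers the configured value; the OU
drift adds a small extra contribution to measured jitter (+~0.02
percentage points) and the jitter adds ~4 cents of per-cycle scatter to
the measured f0 SD — both visible in the round-trip tests and inside
their tolerances.

**Intensity normalization** equalizes RMS across clips (target 0.1 full
scale), preserving within-clip dynamics. Equal RMS (not peak) was chosen
because perceived loudness tracks energy, and it makes normalization
scale-invariant and idempotent.

## 2. Synthetic cohort and EEG forward model

The generator produces the observables the pipeline measures; it makes no
claim of biophysical realism (no volume conduction, no dipoles, no head
model).

**Schedule.** 120 trials (60 vocal / 60 non-vocal, shuffled), stimulus
3.75 s, go signal exactly 5 s after onset (so five 1-s windows tile
onset→go), 5 s production window, spacing chosen so the −1…+5 s
perception and −1…+6 s production epochs of consecutive trials never
overlap.

**Signal model.** Per channel (64 scalp sites on an idealized 2-D layout,
2 mastoids, 1 labial EMG) at 512 Hz, in µV:

* 1/f background, SD 6 µV per channel (FFT-shaped, exponent 1);
* twelve band-limited sources — {fronto-central, centro-parietal,
  parieto-occipital} × hemisphere × {mu: 10±1 Hz, beta: 17.5±2 Hz} —
  each an order-4 Butterworth-filtered noise of SD 9 µV at the region
  centroid, projected through a Gaussian spatial footprint (σ = 0.35
  coordinate units, head radius ≈ 1);
* ERD as *multiplicative amplitude* modulation: depth d scales source
  amplitude by (1−d), hence band power by 1−(1−d)², via logistic
  envelopes whose drop **begins** at the configured onset and completes
  within one ramp (0.5 s default). Default listening ground truth at
  fronto-central sites: vocal onset 1.0 s / depth 0.40 (mu) and 0.30+e
  (beta), non-vocal onset 3.0 s / depth 0.25 (mu), 0.18 (beta), where e
  is the participant's beta "humanness effect"; production ERD is
  strongest centro-parietally (depth 0.45); parieto-occipital sites get a
  mild listening ERS (gain 1.2, mu only).
* mastoids carry reference noise plus a common-mode signal shared with
  all channels (removed exactly by re-referencing); the EMG channel has
  10–100 Hz bursts only inside production windows (SD 30 µV vs 3 µV
  background);
* artifacts: Poisson blinks (0.08 Hz, ~120 µV frontal hanning² bumps,
  0.35 s) and, per epoch window with probability 0.13, one 150–300 µV
  spike on a random channel. The spike rate is set so that, combined with
  the statistical rules, mean surviving perception epochs per condition
  land near the ~51–53 of 60 attrition typical of this paradigm.

Amplitudes (6 µV background, 9 µV sources) are set so that clean-epoch
maxima across 64 channels × 6 s stay below the 100 µV rejection threshold
— with larger, superficially more impressive amplitudes the extreme-value
tail of the clean signal itself trips the amplitude rule.

**Cohort coupling.** Singing inaccuracy (log-normal, median 52 cents,
log-SD 0.35) and the beta humanness effect (log-normal, median 0.15,
log-SD 0.33) are linked by a Gaussian copula whose Pearson parameter
2·sin(πρ/6) yields a population Spearman correlation of the configured ρ
(default 0.49); |ρ| = 1 degenerates to an exact monotone link. Monotone
marginals preserve the rank correlation exactly.

**Sung responses.** Per-note pitch errors are i.i.d. Gaussian in cents
with SD m·√π/2, so the mean absolute produced-interval error converges to
the participant's configured inaccuracy m; a random global transposition
(±100 cents) is added and is invisible to the interval-based score. The
non-vocal condition uses m scaled by 60/52 (the ratio of the paradigm's
typical condition medians). Because that ratio is deterministic, the
synthetic Wilcoxon comparison between conditions is usually significant —
a property of the generator's configuration, not a claim about real
cohorts.

## 3. Preprocessing

Fixed order: high-pass → re-reference → blink removal → epoching →
rejection; identical config and seed give identical masks.

* **High-pass**: 4th-order Butterworth at 1 Hz, applied forward–backward
  (zero phase). At 0.05 Hz the response is −80 dB; at 10 Hz the passband
  is flat to <1%.
* **Re-reference**: every non-mastoid channel minus the algebraic mean of
  the two mastoids; mastoids are dropped downstream.
* **Blink removal** is a documented regression substitute for
  component-based ocular correction: the frontal/EOG channel is low-passed
  at 6 Hz to form a blink reference and each channel's least-squares
  projection onto it is subtracted. 6 Hz keeps >99.5% of a 350 ms blink
  template (so scaled copies cancel to <1% residual power) while leaving
  mu/beta content untouched by construction.
* **Epoching** cuts exact (pre+post)·rate samples per event; a trial whose
  window exceeds the recording is kept but masked with reason `edge`.
* **Rejection** applies three across-epoch rules, reasons recorded in
  fixed order (amplitude, improbability, kurtosis): any |sample| > 100 µV;
  mean negative log-density under a per-channel Gaussian fit to pooled
  samples, z-scored across epochs, > 5 SD; per-channel excess kurtosis
  z-scored across epochs, |z| > 5. Statistics are computed on full epochs,
  scalp channels only (the EMG channel legitimately carries high-kurtosis
  bursts). Note an intrinsic property of across-epoch z-scoring: with n
  epochs a single outlier can reach at most z = (n−1)/√n, so the 5 SD
  rules only bite for n ≳ 27 — with the study's 60–120 epochs they behave
  as intended. Raising any threshold never increases the rejected count.

## 4. Spectral analysis and ERD

**Welch estimator**: Hann windows of 512 samples (1 s), 50% overlap,
density scaling, zero-padded to nfft = 1024 so the grid spacing is exactly
0.5 Hz. Bands: mu 7.5–12 Hz, beta 14–21 Hz; band power is the arithmetic
mean of bins whose centers lie in the closed band.

**Baseline**: the −500…0 ms window is shorter than one analysis window,
so it is estimated with a single 256-point Hann periodogram, zero-padded
onto the same 0.5 Hz grid and band-averaged identically. Padding does not
change spectral resolution, but sampling both estimates on one grid
removes most of the band-edge mismatch that otherwise biases the
subtraction when the in-band signal is narrowband: with the mu source
(2 Hz wide in a 4.5 Hz band) the residual null-modulation ERD bias is
≈ +1 µV²/Hz (≈5% of baseline power), versus ≈ +4.7 µV²/Hz on a coarse
2 Hz baseline grid. This residual is an inherent cost of comparing a
0.5 s baseline to 1 s windows and is why parameter *recovery* (below)
uses within-time-course ratios instead of the subtractive ERD.

**Averaging order** is fixed and logged: trials → electrodes within
region → participants. Baseline subtraction is per trial; a
`condition_mean` mode (subtracting the participant's mean baseline per
condition) is available and leaves all cell means identical. The
subtractive ERD is not scale-invariant: doubling the signal amplitude
quadruples both terms (tested).

**Analysis windows**: perception 0–3.5 s, production 0–5 s, time course =
five 1-s windows tiling 0–5 s; the participant-level humanness effect for
the accuracy correlation uses the 0.25–3.0 s window. Cells with no
surviving trials are emitted as missing (NaN), never zero.

**EMG**: Welch band power 10–100 Hz per epoch, no baseline subtraction.

## 5. Statistics

* **rm-ANOVA** (up to three within factors) by orthonormal-contrast
  projection: for each effect, the Kronecker product of per-factor
  Helmert contrasts (and uniform averaging vectors for the other factors)
  maps each subject's cell vector to effect scores; SS_effect =
  n·‖mean score‖², SS_error = within-subject scatter of the scores, and
  the Greenhouse–Geisser ε = tr(S)²/(df·tr(S²)) from the score
  covariance. Two-level factors have ε = 1 exactly. The corrected p is
  floored at the raw p (with F < 1, shrinking both dfs can otherwise
  *lower* p, which would be nonsense as a sphericity penalty). The
  implementation is cross-checked against two independent references in
  the test suite.
* **Post-hoc**: all pairwise cell comparisons of a named (interaction)
  effect, using that effect's ANOVA error term — Tukey HSD via the
  studentized range, Fisher LSD via an unadjusted t; LSD p ≤ HSD p by
  construction.
* **Wilcoxon signed-rank**: exact null for n ≤ 25 without zeros; zeros
  are rank-split; identical pairs return p = 1 (no evidence either way).
* **Spearman**: midrank rho with a seeded permutation p (default 10⁴
  permutations, add-one estimator) — preferred to the t approximation at
  n ≈ 18–19.
* **Feature regression**: OLS of per-stimulus mean band power on jitter,
  shimmer, f0 variation and median duration, with the overall F test and
  the design's condition number reported.

Each test's type-I error under null simulation is verified to sit inside
the binomial 95% interval around 5% over 1000 replicates.

## 6. Parameter recovery: estimators and what passing shows

* **Onset**: the ERD onset per condition is estimated from the
  fronto-central time course as the first 1-s window whose group-mean
  *power drop relative to the first window* falls below −2 SE (across
  participants) for two consecutive windows. Two deliberate refinements
  over the naive "first window with ERD < −2 SE": (i) the drop-from-w1
  statistic cancels the baseline estimate, whose sampling noise is shared
  by every window of a trial and otherwise correlates the window tests
  (making them false-fire together in a few percent of small cohorts);
  (ii) 2-window persistence suppresses single-window flukes. The first
  window is pre-onset for every configured ground truth; an onset inside
  w1 would not be resolvable by this estimator.
* **Depth**: the fractional band-power drop is measured as 1 − P_w5/P_w1
  (last vs first window, identical spectral resolution, per participant,
  then averaged) and compared with the configured 1−(1−d)². Measured
  drops sit ~15–20% below the configured values because the fronto-central
  electrodes also carry unmodulated power (background, cross-region
  leakage) — inside the 30% recovery tolerance, and a reminder that the
  recovery checks validate the *pipeline*, not absolute calibration.
* **Coupling**: the cohort generator's inaccuracy–effect Spearman ρ is
  recovered as the mean empirical rank correlation over many cohort
  draws.

Recovery is asserted over 50 reduced cohorts (6 participants, 30 trials
each) — sizes chosen to exercise the full chain at a few seconds per
simulated participant — plus 500 fast cohort draws for the coupling.

## 7. What the generator does not emulate

No volume conduction or realistic topographies (Gaussian footprints on an
idealized layout), no non-stationary background (the 1/f floor is
statistically stationary outside the ERD envelopes), no eye-movement
artifacts other than blinks, no line noise, no muscle contamination of
scalp channels, no inter-trial dependence, and no model of real singers'
error structure beyond i.i.d. per-note pitch errors. Passing tests
therefore demonstrate that the pipeline measures what it claims on data
obeying its assumptions; they do not certify performance on real
recordings, where artifact morphology and source geometry are richer.

## 8. File formats

Recordings travel as 16-bit EDF (1-s records, per-channel physical range,
trailing partial record dropped) with events in a CSV sidecar
(onset_s, label, trial_index) that round-trips exactly; the writer is
validated against an independent EDF reader. Audio is 32-bit float WAV
with a note-boundary CSV sidecar. Tables are tidy CSV; every pipeline
output embeds the run-config hash and seed.
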