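# Methods

`betarebound` implements a complete analysis chain for EEG experiments in
which peripheral somatosensory stimulation (here: electrical stimulation of
the lower lip) is paired with auditory syllable presentation, and the
question is whether the post-stimulus dynamics of the central sensorimotor
rhythms — mu (8–12 Hz) and beta (13–30 Hz) — depend on the *place of
articulation* of the heard syllable.  The physiological signature of
interest is the event-related desynchronization / synchronization (ERD/ERS)
pattern: a transient power drop roughly 200–400 ms after the event,
followed by a rebound above baseline from about 500 ms.  The headline
hypothesis is articulator-specific interference: when the syllable is
produced with the lips (bilabial) *and* the lips are stimulated, the beta
rebound over the left central electrodes is attenuated, because the same
somatosensory population is busy processing the speech sound.  Statistically
this is a syllable × stimulation × time-window interaction in the beta band
of the left region of interest (ROI).

## Analysis chain

1. **Preprocessing** — zero-phase 4th-order Butterworth band-pass
   0.5–50 Hz (EEG channels only), resampling to 250 Hz, common average
   reference over the EEG channels (EOG excluded), epoching −1.5 … +2.5 s
   around vowel onset (half-open convention, 1000 samples at 250 Hz), and
   baseline correction over −1000 … −150 ms.  Filtering, resampling and
   epoching are delegated to MNE-Python; the resampler is MNE's standard
   FFT-based anti-aliased implementation.  Trials too close to a recording
   edge are excluded with a logged warning.

2. **Behavioural scoring** — responses are horizontal saccades.  The
   bipolar EOG difference (right − left canthus electrode) is low-pass
   filtered at 20 Hz (zero-phase Butterworth, order 4) and a 3 s window
   from question onset is scanned.  The first excursion exceeding 1.5
   standard deviations from the window average is the response; its sign
   gives the direction (positive → rightward).  A first excursion earlier
   than 150 ms counts as anticipation and invalidates the trial, as does
   the absence of any excursion.  Whether the mean/SD statistics come from
   the trial window (default) or from session-level statistics is
   configurable; the window statistic is the natural reading of a per-trial
   detector and is what the defaults use.  Reaction time is read at the
   threshold crossing, which on band-limited noise-free signals recovers
   the onset to within one sample.  Incorrect and invalid trials are
   discarded before any spectral analysis.

3. **Time–frequency decomposition** — complex Morlet wavelets on a
   4–40 Hz grid in 0.5 Hz steps (73 frequencies), with the cycle count
   rising linearly from 3 cycles at 4 Hz to 20 cycles at 40 Hz.  Kernels
   are L2-normalized, with Gaussian envelope SD `n(f) / (2πf)` and support
   truncated at ±5 SD, applied by FFT convolution ('same' alignment); the
   spectral path is verified against direct time-domain convolution to
   1e−9 relative error.  The event-related spectral perturbation is

       ERSP(f, t) = 10·log10( meanₖ |Wₖ(f, t)|² / P₀(f) ),

   with `P₀(f)` the power averaged over trials *and* baseline time points
   (−1000 … −150 ms): one common divisor per frequency rather than
   per-trial normalization, matching the standard definition of a
   baseline-relative dB map.  Output maps cover −1000 … +1000 ms.  ROI
   maps average the per-electrode dB maps over the left (C1, C3, C5) or
   right (C2, C4, C6) central electrodes; averaging the voltage first and
   decomposing the virtual channel is available behind a flag
   (`mode="average_voltage"`), but dB-averaging is the default because it
   is insensitive to phase cancellation between electrodes.

   *Edge handling.*  With a −1.5 s epoch start, a −1 s output start and 3
   cycles at 4 Hz, a ±5 SD safety margin cannot be satisfied at the lowest
   frequencies (5·σ_t = 0.60 s > the 0.5 s available).  Kernels therefore
   keep their ±5 SD support, while the edge-safety *check* requires ±3 SD
   (99.7 % of the envelope energy) inside the epoch, configurable via
   `MorletSpec.edge_sigma`.  Violations raise an error naming the
   offending frequency.

4. **Map-level statistics** — condition contrasts (dental vs bilabial,
   separately per stimulation level and ROI) use a paired t statistic
   across subjects at every (frequency, time) point.  The null is built by
   sign-flipping each subject's difference map: under the null of no
   condition difference the paired differences are symmetric around zero,
   so the 2ⁿ sign patterns are exchangeable.  When the requested
   permutation count covers all 2ⁿ patterns the null is enumerated exactly
   (with n = 12 subjects that is 4096 patterns); otherwise random patterns
   are drawn and p = (1 + exceedances) / (n_perm + 1), so p-values are
   never zero.  Because sign flips leave the squared differences
   unchanged, permuted t values are computed from permuted means alone,
   which makes the full map test cheap.  Multiplicity across the
   73 × 501 grid is handled by Benjamini–Hochberg FDR (default q = 0.01),
   via `statsmodels`.  A trial-level alternative (condition-label
   shuffling with Welch t) is provided for designs without subject-level
   pairing, but subject-level inference is the default: it matches the
   degrees of freedom of the reported group tests.

5. **Baseline significance** — to flag where a single map deviates from
   its own baseline, a bootstrap draws one baseline time point per trial,
   recomputes the trial-averaged power per frequency, and repeats this
   (default 10 000 times) to form a per-frequency null distribution of
   baseline-only dB values; the observed map is flagged outside the
   two-tailed percentile band.  This scheme is a documented reconstruction
   of the classical "significance versus baseline" bootstrap used by
   EEG time–frequency toolboxes, which is not fully specified in the
   literature; its false-positive rate is verified by simulation.

6. **Band/window ANOVA** — per subject and condition, the ERSP map is
   averaged over band × window regions: ERD at 200–400 ms for both bands,
   ERS at 400–600 ms for mu and 600–800 ms for beta.  The 2 × 2 × 2 fully
   within-subject ANOVA (syllable × stimulation × window) is computed from
   ±1 contrast scores: for every effect, the per-subject score is the
   contrast-weighted cell mean, and F = (mean / SE)² with df (1, n − 1).
   This is algebraically identical to the classical sums-of-squares
   decomposition with effect-specific error terms (verified to 1e−8
   against an independent oracle) and to the squared paired t of the
   contrast.  The engine is factor-label agnostic and is reused unchanged
   for the reaction-time ANOVA (syllable × stimulation × question
   polarity).  Post-hoc comparisons are two-tailed paired t tests with
   Bonferroni correction (two comparisons → α = 0.025 at a family level
   of 0.05); degenerate pairs report p = 1 with a warning.

## Synthetic data generator

No public data accompany this problem, so the generator is a first-class
module that produces continuous recordings with the statistical structure
the analysis assumes.

* **Design**: 6 speakers × 2 syllables × 8 repetitions × 2 stimulation
  levels = 192 trials (96 stimulated), pseudo-randomized, question 1.5 s
  after vowel onset, 7–8 s inter-trial interval after a 4.5 s trial span,
  yes/no question polarity balanced within every syllable × stimulation
  cell, response sides counterbalanced across subjects.
* **Background**: 1/f-power noise (white spectra shaped by f^−1/2),
  default 8 µV SD per channel, on all 8 EEG channels (C1–C6, Cz, Pz) and
  both EOG channels (5 µV).
* **Oscillators**: narrowband mu (10 Hz, 5 µV) and beta (20 Hz, 4 µV)
  processes on the six central channels.  Each is a unit-envelope cosine
  whose instantaneous frequency wanders slowly (band-limited drift, SD
  0.75 Hz within 2 Hz), which decorrelates the phase across trials — the
  ERD/ERS lives in induced, not evoked, power — while keeping the
  amplitude exactly constant, so envelope-gain contracts can be tested to
  1 %.
* **Event-locked dynamics**: around each vowel onset the oscillator
  envelope follows a profile with raised-cosine ramps (50 ms): gain 1 in
  baseline, 0.6 in the ERD window (200–400 ms), 1.75 in the ERS window
  (500–800 ms).  Stimulation-absent trials keep 40 % of the excursion
  (the auditory event alone modulates the rhythms more weakly).  On
  bilabial + stimulation trials the *beta* ERS excursion is attenuated by
  a factor 0.8, weighted per channel by the lateralization vector
  (default: 1 on C1/C3/C5, 0 on C2/C4/C6).  The attenuated fraction is a
  property of the condition; its absolute size scales with each subject's
  rebound.
* **Variability**: lognormal per-trial amplitude jitter (SD 0.2), a
  per-subject scale on all envelope excursions (SD 0.25), Gaussian
  saccade-latency noise (SD 80 ms) around a 531 ms mean with small
  polarity (±24.5 ms) and stimulation (±11 ms) effects, and a 13.1 %
  probability of executing the wrong saccade.
* **Calibration**: amplitudes and gains were fixed once so that the
  pipeline's group dB values land in the ±0.5 … ±2 dB range typical of
  central ERD/ERS studies, with a condition effect of moderate size
  (per-dataset interaction F values of order 10–40 at the reduced session
  size below); they are study conditions, not tuning knobs.

What the generator does **not** emulate: eye-blink/EMG/line artifacts and
their ICA cleanup (the analysis assumes artifact-free input; an optional
line-noise flag exists), volume conduction and realistic channel
covariance (channels carry independent oscillator phases), evoked
(phase-locked) components such as the somatosensory evoked potential, and
non-stationary drifts of the background spectrum.  Passing tests therefore
demonstrate the correctness and calibration of the *analysis*, not the
realism of scalp EEG in every respect.

## Problem sizes used in the simulation studies

The repeated simulation studies (parameter recovery, type-I calibration)
use a reduced session — 4 speakers × 4 repetitions = 64 trials (16 per
cell), inter-trial intervals of 1–1.5 s — with the full 12-subject group
and the complete pipeline per dataset; 50 datasets for the recovery study,
150–200 synthetic-map datasets with 1000 sign-flip permutations for the
null calibration.  These sizes were chosen so that a study runs in seconds
while the group-level degrees of freedom (df = 11) match the full design.
The permutation default inside the pipeline is 1000; the module-level
default for a standalone map contrast is 10 000.

## Numerical and degenerate-input choices

* Permutation p-values are floored at 1/(n_perm + 1) (sampled) or are
  exact multiples of 2⁻ⁿ (enumerated); ties count as exceedances
  (`t_perm ≥ t_obs − 1e−12`).
* Zero baseline power, empty factor cells, missing ROI channels,
  out-of-grid band/window regions and out-of-range wavelet frequencies
  raise typed errors; an all-zero paired difference yields t = 0 and
  p = 1, never NaN.
* The EDF+ writer quantizes to 16 bit over a per-channel symmetric range
  rounded to its header text, so the written scale is exactly the declared
  one; round-trips through MNE's EDF reader agree to the quantization
  step (~0.003 µV on a ±100 µV channel).
* Epoch sample counts use the half-open [start, end) convention
  (4 s × 250 Hz = 1000 samples).
* All randomness flows from explicit seeds; sub-seeds are derived by
  hashing (master seed, index, stream) through `numpy.random.SeedSequence`
  so that adjacent master seeds give statistically independent studies.

## Known limitations

* The baseline-significance bootstrap is a reconstruction (see above);
  other toolboxes may implement a different resampling unit.
* Subject-level sign-flip inference assumes symmetric difference
  distributions; with n = 12 the exact enumeration bound limits the
  smallest achievable p to 2·2⁻¹² two-tailed.
* The detector reads RT at the threshold crossing of a 20 Hz-low-passed
  signal; absolute RTs carry a small filter- and threshold-dependent bias
  (~10–20 ms), which cancels in within-subject contrasts.
* ICA-based artifact removal is out of scope; real recordings must be
  cleaned before entering the pipeline.
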