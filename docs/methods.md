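# Methods

This note documents the models, numerical choices and limitations behind
`oculoflow`. It describes what the code computes; every number quoted here
is produced by the test suite or `scripts/acceptance.py` at run time.

## The paradigm being emulated

Each trial of the mental-multiplication paradigm shows a multiplication
sign at screen center for 2 s, a two-digit operand for 300 ms, a one-digit
operand for 300 ms, and then a blank calculation period that ends when the
participant clicks (median RT around 2.7 s). Reading the operands is
externally directed cognition (EDC); calculating in mind is internally
directed cognition (IDC). Sessions have two blocks: one without
distractors and one in which a number flashes for 500 ms at one of eight
positions on a 150 px circle, with onset 1.0, 1.5, 1.75, 2.0 or 2.25 s
after calculation onset (1.0 s onsets are catch trials, excluded from eye
analyses). Each block contains 18 multiplication and 4 passive-viewing
trials. Six eye parameters are analyzed in four 500 ms bins spanning
−0.5 s to +1.5 s around calculation onset: blink rate, saccade rate,
microsaccade rate, fixation disparity, pupil diameter, and gaze-at-center.

## Synthetic recording generator

The generator exists so that every downstream stage is testable against a
known ground truth without any recorded data. Per trial it emits 250 Hz
binocular gaze (pixels; origin top-left, center 960/540, 45 px/deg) and
pupil diameter (mm), plus an exact event log.

Signal model and defaults (all configurable in `SimulationConfig`):

- **Fixational drift**: 2-D Gaussian random walk, step SD 0.004 deg per
  sample. **Tremor/tracker noise**: white, 0.015 deg per eye and axis
  (about the spatial resolution of research-grade remote trackers).
- **Saccadic events**: Poisson processes — microsaccades at 1.2 Hz over
  the whole trial, larger saccades at 0.5 Hz during the calculation period
  only (eye activity increases during IDC). Amplitudes are lognormal
  (median 0.4 deg, sigma 0.45 for microsaccades; median 3 deg, sigma 0.5
  for saccades). Each event displaces gaze along a raised-cosine position
  profile in a uniformly random direction, and the displacement persists.
- **Main sequence**: ground-truth peak velocity is exactly
  `main_sequence_slope * amplitude` (default 60 (deg/s)/deg). A raised
  cosine of amplitude A and duration D has peak velocity piA/(2D), so the
  exact linear main sequence fixes the event duration at
  D = pi/(2*slope) ~ 26 ms, independent of amplitude. We chose to keep the
  linear relation exact (it is the property the detector-recovery tests
  lean on) rather than an amplitude-dependent duration; real saccade
  durations grow with amplitude, which this generator does not reproduce.
- **Blinks**: Poisson at 0.25 Hz, uniform duration 100–300 ms; gaze and
  pupil of both eyes are invalid (missing) for the span. Events of all
  kinds are placed without overlap (each keeps its drawn Poisson count by
  re-drawing its onset), so injected counts remain Poisson-distributed.
- **Vergence**: white fixation-disparity noise, SD 0.3 mm, split evenly
  across the eyes' horizontal positions.
- **Pupil**: baseline 4 mm; during multiplication trials a linear ramp
  rising over the first second of calculation and saturating at +0.3 mm
  (task-evoked dilation); a 0.1 mm raised-cosine transient of width 1 s
  follows distractor onset; white per-eye noise 0.02 mm.
- **Behaviour**: P(correct) = 0.85 per multiplication trial, 45% of errors
  are "forgot"; RT lognormal with median 2.65 s, sigma 0.35, floored at
  1.6 s so the four analysis bins always fit inside the recording.
- **Reproducibility**: all draws come from substreams seeded as
  `(seed, participant, trial_index)`, so trial order never changes draws
  and identical configurations are byte-identical.

What the generator does *not* emulate: amplitude-dependent saccade
durations and post-saccadic oscillations, corrective return saccades,
1/f pupil noise and the pupil light reflex, smooth pursuit, head motion,
and tracker-specific noise spectra. Passing recovery tests therefore show
that the detector implements its criterion correctly at realistic noise
levels, not that it would reach the same recovery on any real recording.

## Preprocessing

Blinks are maximal runs of invalid pupil (either eye) of at least 3
samples (12 ms; rejects single dropped samples). Each blink plus 2 samples
(8 ms) on each side is masked. Samples with pupil diameter > 15 mm or
< 1.8 mm, or |fixation disparity| > 60 mm, are masked as extreme; then a
per-participant rule masks samples whose binocular pupil or disparity lies
beyond the participant's mean ± 3 SD, with the statistics computed over
the whole session after blink and range masking (the order — SD rule after
blink padding — is our choice; sources differ). Masked samples are
dropped, never interpolated. Discard rates are reported as two separate
percentages on disjoint denominators: blink discard over all samples,
extreme/SD discard over the non-blink remainder.

## Event detection

The detector is the standard median-based velocity-threshold algorithm of
fixational-eye-movement research. Velocity comes from the 5-point
moving-average differentiator v_n = (x_{n+2} + x_{n+1} − x_{n−1} −
x_{n−2}) / (6 dt), exact on linear signals; samples whose window touches a
masked gap have undefined velocity. Per trial and eye, the threshold is
eta = lambda * sigma with sigma^2 = median(v^2) − median(v)^2 per
component (robust to the saccades themselves) and lambda = 6. Events are
maximal runs of at least 2 samples (8 ms) with (v_x/eta_x)^2 +
(v_y/eta_y)^2 > 1 (strict; ties are sub-threshold). Amplitude is the
start-to-end displacement, not path length. Binocular events require at
least 1 sample of temporal overlap between the eyes; the merged event
spans the union interval and averages the two monocular amplitudes and
peak velocities, pairing each right-eye event with at most one left-eye
event by maximal overlap. Events containing any masked sample are
discarded rather than truncated. Amplitude ≤ 1.5 deg classifies an event
as a microsaccade (boundary inclusive). Thresholds are estimated per trial
per eye; estimating per participant instead would pool across trials and
is not implemented.

## Binned parameters and baseline correction

Bins are half-open [start, end) by event-onset time; at 250 Hz each 500 ms
bin holds exactly 125 samples. Rates are onset counts times 2 (per-second
units). Pupil and disparity are medians over samples that are unmasked and
outside every detected blink/saccade/microsaccade; disparity is
(right − left horizontal gaze) converted at 531 mm / 1920 px, negative =
convergent. Gaze-at-center uses the cyclopean (two-eye mean) gaze within
1 deg of center; its denominator is the full bin (masked samples count
there but never in the numerator). Baselines are subtracted trial-wise:
medians of the 500 ms before the first operand for pupil and disparity;
mean rate (or percentage) over the whole 2 s sign window for the three
rates and gaze-at-center. Bins or baselines with no eligible samples
propagate as missing, never zero-filled. Distractor-locked epochs apply
the same machinery in (−0.5, +1.0) s around distractor onset with a 500 ms
pre-distractor baseline.

## Trial filtering and statistics

Eye analyses keep correct, non-catch multiplication trials with RT within
the participant's mean ± 3 SD (RT statistics pooled over both blocks over
correct non-catch trials; skipped below 2 trials), and valid
passive-viewing trials pooled across blocks. Participants answering
passive trials with a solution are excluded wholesale. Performance
percentages per block are computed over all multiplication trials,
including catch trials (our choice; the denominator convention is not
fixed by the design).

The paired t test reports two-sided p, Bonferroni correction
p_corrected = min(1, k·p) with k = 4 tests per eye parameter, and
d_z = t/sqrt(n). The JZS Bayes factor integrates the noncentral-t
likelihood against a Cauchy(0, r = 0.707) prior on the standardized
effect, via the substitution delta = r·tan(theta) and adaptive quadrature
(relative tolerance 1e−6); BF01 = 1/BF10, and the value is invariant to
the sign of t. The two-way repeated-measures ANOVA (condition × time,
within subjects) reports uncorrected degrees of freedom — (2, 70),
(3, 105) and (6, 210) with 36 participants — and generalized eta squared;
Greenhouse–Geisser correction is available as an option. ANOVA-level
Bayes factors are not provided: the reference tools compute them by Monte
Carlo and they are not reproducible to fixed precision. Power for the
paired t test is exact under the noncentral t distribution with
noncentrality d_z·sqrt(n); required sample size is the smallest n whose
power reaches the target (upward integer scan).

## Problem sizes used by the test and acceptance runs

Deterministic statistical targets (Bayes factors, power, d_z) use the
published inputs directly. Detector/oracle equivalence runs 50 seeded
traces of 400–2000 samples; ground-truth recovery runs three simulated
default sessions (132 trials); Monte-Carlo calibration uses 10^4
replicates at n = 36; pipeline-determinism runs use 2 participants with 6
multiplication + 2 passive trials per block. These sizes were chosen to
give tight Monte-Carlo bounds while keeping a full test run around half a
minute.

## Known limitations

- The simulator's oculomotor parameters are literature-plausible
  conventions, not fits to any dataset; effect *sizes* in simulated
  statistics are arbitrary.
- Constant saccade duration (see main-sequence note above).
- No pupil foreshortening correction, no gap interpolation, no smooth
  pursuit or post-saccadic oscillation handling.
- Velocity thresholds are per trial; very short trials give noisier
  thresholds.
- The correlation table treats trial × bin cells as observations;
  within-participant dependence is not modelled.
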