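# Methods

## Overview

`nfsonic` models a connectivity-based neurofeedback protocol as a
deterministic per-sample pipeline: a two-ROI BOLD source (simulated or
loaded from TSV) → causal sliding-window Pearson correlation → active or
sham displayed value → chord rendering → MIDI. Real-time behaviour is
modelled logically (one update per TR) rather than with wall-clock
scheduling; the scanner-side transport (DICOM export, real-time GLM, ROI
definition, TCP/IP streaming, audio synthesis) is out of scope, and MIDI
events are the terminal audio representation.

## Task schedules

Two run types are built on a continuous time axis sampled at
TR = 1.5 s:

* **Localizer** — per trial: rest 6 s, motor imagery 10 s, music 10 s,
  noise 10 s, pleasantness report 6 s, abutting; six trials give exactly
  252 s. An optional inter-trial pad (default 0 s) is provided rather
  than silently stretching the printed block durations.
* **Neurofeedback** — alternating rest/imagery blocks starting with
  rest. The rest duration and trial count per run are configurable;
  defaults are 30-s rest, 4 trials per run (symmetric blocks make the
  imagery and rest block-locked time courses directly comparable).
  Block durations off the TR grid are rounded down with a warning so
  block boundaries always fall on sample boundaries.

Sample-to-block assignment uses half-open intervals
[onset, onset + duration): a sample exactly on a boundary belongs to
the later block, and samples outside every block are labelled rest.
Beep cues fall at each imagery block's midpoint. Schedules serialize to
BIDS-style `events.tsv` (onset, duration, trial_type).

## Synthetic BOLD model

Each ROI i ∈ {L, R} is generated as

    n_i(t) = a(t) · ( √ρ(t)·s(t) + √(1−ρ(t))·e_i(t) )
    y_i(t) = (h ∗ n_i)(t) + β·t + ε_i(t)

with s, e_L, e_R independent unit-variance white Gaussian sequences, so
the neural-level interhemispheric correlation equals ρ(t) exactly in
expectation; h is the canonical double-gamma HRF (peak ≈ 5–6 s,
1/6-amplitude undershoot at 16 s, 32-s support, unit peak); β is a
linear drift (default 0.01 units/sample); ε is AR(1) measurement noise
(default stationary SD 0.5, lag-1 coefficient 0.3).

Parameter choices and what they mean:

* **ρ per condition** — imagery 0.7, rest 0.1 (music 0.2, noise/report
  0.1 for localizer runs). These are the default study conditions:
  strong coupling during bimanual motor imagery, weak spontaneous
  coupling at rest. The rest level is a free choice; no empirical value
  is asserted for it.
* **Amplitude a(t)** — 1.0 in every condition by default: the modulated
  quantity in this protocol is the coupling, not the activation level,
  and a constant amplitude keeps the measurement attenuation
  (signal/noise variance ratio) identical across conditions. The
  `taper_second_half` flag halves imagery amplitude after the beep to
  emulate the instructed slow-down; it is off by default.
* **Noise** — AR(1) + linear drift approximate scanner noise.
  Physiological (cardiac/respiratory) confounds are not simulated: in
  the protocol being modelled they are handled by offline GLM
  denoising, which is out of scope here.

Because both ROIs pass through the same linear filter, the HRF preserves
the stationary neural correlation but autocorrelates the series, so
short-window sample correlations are noisy and block transitions bleed
across boundaries — the generator reproduces the *ordering* of coupling
levels faithfully (tested), not their exact values.

Cohorts follow the crossover layout: `runs_per_subject` = 4, even
subject indices sham-first, odd active-first. Per-subject imagery and
rest coupling are jittered by a clipped Gaussian (SD 0.05) to create
between-subject variability. All seeding flows through
`numpy.random.SeedSequence` spawning, so cohorts are bit-reproducible.

What passing tests on this generator do **not** show about real data:
no spatial structure, no motion or physiological artefacts, no
non-stationary coupling within a condition, and Gaussian marginals
throughout. Statistical calibration results (type-I, power) are
statements about this generative model at the configured effect sizes.

## Windowed correlation

`sliding_corr` computes, at every sample t ≥ w−1, the Pearson
correlation of the w most recent samples *including* t (default w = 8
samples). The window is specified in samples, not seconds: the
real-time software's unit of operation is the acquired sample, and a
causal window acting on the newest sample minimizes feedback latency.
Samples before the first full window are invalid; windows with (near-)
zero variance in either channel (relative tolerance 1e−12) are invalid
rather than NaN or 0, because the correlation is undefined there —
downstream feedback holds the previous chord instead of punishing the
participant with an arbitrary value. Fisher z = artanh(r) is applied
after clipping r to ±0.999999 so degenerate perfect correlations stay
finite. Raw r drives the sonifier; z is used by all statistics.

## Sonification

* Tonic set: the ten pitches are configurable; the default is the
  C-major scale from C3 spanning a tenth (48 50 52 53 55 57 59 60 62
  64) — diatonic, ascending, perceptually ordered. The protocol defines
  ten bins but not the actual pitches.
* Consonant quality: tonics on scale degrees I and IV take maj7, all
  others min7 (`consonant_mode="diatonic"`); `"maj7"` forces major
  7th everywhere. This keeps consonant feedback inside one key.
* Tie rule: r equal to the previous value counts as an increase
  (consonant) — sustained high correlation is not punished.
* Each imagery block's first chord is compared against its own r, so
  blocks open consonant.
* Rest is represented by one white-noise cue marker per contiguous rest
  segment (the cue is a continuous sound, not a per-TR event); the beep
  is a marker at each imagery midpoint. No audio is synthesized.
* Sham feedback is a reflected Gaussian random walk on [0, 1] with step
  SD 0.5·(1−smoothness), default smoothness 0.8 (per-TR steps ≈ 0.1).
  A smooth walk sounds musically plausible — a requirement for
  participant blinding — while remaining a pure function of its seed
  and hence independent of the brain signal. `smoothness=0` degenerates
  to i.i.d. uniform draws. The initial value is drawn before the step
  sequence so a truncated run consumes an identical RNG prefix
  (causality of the sham stream).

MIDI output is a format-0 Standard MIDI File at 480 ticks per quarter
and a fixed 120 BPM tempo; each chord is four note-on/note-off pairs,
cues are text meta events. At this resolution one tick ≈ 1.04 ms, so a
write/read round trip is exact at tick resolution (tested). The
writer/reader is part of the package and covers exactly this event
vocabulary.

## Statistics

* **Wilcoxon signed-rank** (paired): zero differences are dropped —
  Wilcoxon's original treatment and the common package default; the
  policy is a documented choice, and results on borderline data can
  depend on it. For n ≤ 12 remaining pairs the exact permutation null
  (all 2ⁿ sign flips, mid-ranks for ties) is enumerated; above that,
  the normal approximation with continuity and tie corrections. The
  statistic is the positive-rank sum (one-sided) or the smaller signed
  rank sum (two-sided).
* **Mann-Whitney U**: exact permutation null for combined n ≤ 12
  (mid-ranks for ties), normal approximation with tie correction above.
* **Holm-Bonferroni**: step-down adjustment with running-maximum
  monotonicity, capped at 1.
* **Modulation tests**: per-subject mean imagery z (active runs, sham
  runs) vs mean rest z; one-sided tests corrected by a factor 2 (the
  active and sham comparisons), exposed as a parameter.
* **Per-timepoint tests**: paired Wilcoxon at each within-block offset
  of the block-locked mean-z time course, correction factor 2. An
  offset where every subject has a zero difference reports p = 1
  rather than erroring (the bare Wilcoxon op does error on all-zero
  input).
* **Effect size** r = |z|/√n is computed from the normal-approximation
  z statistic even when the p value is exact, matching common reporting
  practice.
* **Association**: OLS slope/intercept with Pearson r and its two-sided
  p (scipy `linregress`).

The exact small-n branches are backed by `scipy.stats` permutation
methods; the test suite checks them against independent brute-force
enumerations written from scratch.

## Calibration experiments and problem sizes

The acceptance script and test suite run two simulation studies, both
with 22-subject cohorts of four 240-s runs (160 samples each):

* **Type-I error**: coupling 0.1 in *all* conditions. Note that a true
  null requires equal amplitudes as well as equal coupling — with
  unequal amplitudes the measurement attenuation would differ between
  conditions and the measured correlations would differ under equal
  neural coupling. 500 seeded replications; the one-sided test at
  α = 0.05 must reject at the nominal rate within the binomial 95%
  interval (±1.9 percentage points).
* **Power**: default coupling (imagery 0.7, rest 0.1), 100
  replications; the corrected test must reject in ≥95% and the cohort
  mean imagery z must exceed rest z in every replication.

Sham-independence checks use 10⁴-sample runs: both the sham walk and
the windowed metric are strongly autocorrelated, so the sample
correlation between two independent smooth series needs many effective
degrees of freedom before a tight bound (|r| < 0.1) holds with high
probability; the run length is chosen to make that sampling bound
reliable, and 50 seeded runs are required to satisfy it in ≥48.

## Known limitations

* The generator's coupling is piecewise-constant per condition; real
  connectivity modulation is gradual and strategy-dependent.
* The sham walk is not matched to the temporal statistics of real
  feedback traces beyond smoothness; blinding adequacy is a perceptual
  claim the simulation cannot test.
* The localizer's printed block durations sum to 252 s for six trials;
  any additional dead time in a real session (baseline, gaps) must be
  expressed through the pad parameter.
* Exact tests switch to the normal approximation above n = 12; for
  n just above the cutoff, p values near α can differ from the exact
  ones by more than their distance to α.
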