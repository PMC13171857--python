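# nfsonic

**Connectivity-to-music fMRI neurofeedback engine.** During motor
imagery, the interhemispheric functional connectivity of the premotor
cortex (PMC) — the windowed Pearson correlation *r* between the left and
right PMC BOLD signals — is translated, once per repetition time
(TR = 1.5 s), into a harmonic chord progression the participant hears as
feedback. `nfsonic` implements that translation, the closed active/sham
feedback loop around it (simulated offline, one update per TR), a
synthetic two-ROI BOLD generator that stands in for the scanner, and the
offline nonparametric statistics used to judge modulation success.

It is aimed at neurofeedback researchers who want to prototype, test, or
teach connectivity-sonification protocols without a scanner in the loop.

## The feedback mapping

At each TR *t* the engine computes the causal windowed correlation over
the last *w* samples (default *w* = 8),

    r_t = corr( L[t-w+1 .. t], R[t-w+1 .. t] ),

and renders it as a four-note seventh chord:

* **Base note (tonic):** *r* is clipped to [0, 1] and split into ten
  0.1-wide bins, `bin = min(⌊10·r⌋, 9)`; each bin indexes one of ten
  ascending tonic pitches (default: C-major scale degrees C3…E4).
  Higher correlation ⇒ higher base note.
* **Chord quality:** if `r_t ≥ r_{t-1}` the chord is consonant — major 7th
  on scale degrees I and IV, minor 7th otherwise (diatonic
  harmonization, configurable) — and if `r_t < r_{t-1}` it is a
  dissonant diminished 7th. Musical pleasantness therefore tracks the
  *change* in connectivity while pitch height tracks its *level*.

Chords sound only during 30-s motor-imagery blocks (one chord per TR,
emitted as MIDI note events); rest is cued by a white-noise marker, and
a beep marker halfway through each imagery block tells the participant
to wind the imagined movement down. Sham runs replace *r* with a seeded
smoothed random walk on [0, 1], independent of the brain signal, in a
crossover design (half the subjects get sham first).

For statistics, correlations are Fisher-transformed, *z* = artanh(*r*),
and modulation success is the per-subject mean *z* during imagery
(active and sham runs separately) against rest, compared with one-sided
paired Wilcoxon signed-rank tests corrected for the two comparisons.
The battery also includes Mann-Whitney U (chord pleasantness ratings),
Holm-Bonferroni-corrected pre/post comparisons with effect size
r = |z|/√n (mood subscales), per-timepoint block-locked tests, and an
OLS behaviour–success association.

## Worked example

```python
from nfsonic import build_nf_schedule, simulate_pair, run_loop, SimConfig
from nfsonic.stats import cohort_success, modulation_tests
from nfsonic.synthbold import simulate_cohort

# one neurofeedback run: 4 × (30 s rest + 30 s imagery), TR 1.5 s
sched = build_nf_schedule()
sim = simulate_pair(sched, SimConfig(seed=42))     # imagery ρ=0.7, rest ρ=0.1
rec = run_loop(sim, mode="active")
for c in rec.chords[:5]:
    print(f"t={c.onset:6.1f}s  bin={c.bin}  tonic={c.tonic}  {c.quality:5s}  pitches={c.pitches}")

cohort = simulate_cohort(22, seed=1)               # 22 subjects × 4 crossover runs
table = cohort_success(cohort)
for g in modulation_tests(table):
    print(f"{g.comparison}: W={g.statistic:.1f}, p_corrected={g.p_corrected:.5f} "
          f"(median {g.median_a:.3f} vs {g.median_b:.3f})")
```

prints

```
t=  30.0s  bin=1  tonic=50  min7   pitches=(50, 53, 57, 60)
t=  31.5s  bin=2  tonic=52  min7   pitches=(52, 55, 59, 62)
t=  33.0s  bin=3  tonic=53  maj7   pitches=(53, 57, 60, 64)
t=  34.5s  bin=3  tonic=53  maj7   pitches=(53, 57, 60, 64)
t=  36.0s  bin=5  tonic=57  min7   pitches=(57, 60, 64, 67)
active NF vs rest: W=251.0, p_corrected=0.00006 (median 0.574 vs 0.314)
sham NF vs rest: W=253.0, p_corrected=0.00004 (median 0.560 vs 0.314)
```

The first imagery block opens at t = 30 s; rising correlation walks the
tonic up (bins 1→2→3→5) with consonant qualities, and a repeated bin at
t = 34.5 s re-sounds the same chord because the correlation held its
level. At the cohort level the mean imagery Fisher z (≈0.57) clearly
exceeds rest (≈0.31) under the default generative coupling, and both
corrected Wilcoxon tests reject.

A `nfsonic` command-line tool wraps the same pipeline
(`schedule`, `simulate`, `sonify`, `run-loop`, `analyze` subcommands);
run `nfsonic --help`.

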