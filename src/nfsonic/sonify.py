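"""Correlation → chord-progression feedback.

The feedback mapping has two axes:

* **Tonic (base note)** — the correlation level in [0, 1] is split into
  ten 0.1-wide bins; each bin indexes one of ten ascending tonic pitches,
  so higher interhemispheric correlation sounds as a higher base note.
* **Quality** — the correlation *change* relative to the previous
  feedback sample picks the chord type: non-decreasing → consonant
  (major 7th or minor 7th), decreasing → dissonant diminished 7th.

Chords are emitted once per TR during motor-imagery blocks only; rest is
cued by a white-noise marker and the mid-block beep by a beep marker.
Sham runs replace the brain-derived correlation with a seeded smoothed
random walk that is statistically independent of the BOLD input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import midi
from .connectivity import CorrTrace
from .paradigm import RunSchedule, beep_times, labels_per_sample

__all__ = [
    "SonifyConfig",
    "ChordEvent",
    "CueEvent",
    "corr_to_bin",
    "quality_from_delta",
    "chord_pitches",
    "render_run",
    "sham_trace",
    "write_midi",
    "events_to_frame",
]

#: Default tonic set: C-major scale degrees spanning a tenth from C3.
DEFAULT_TONICS = (48, 50, 52, 53, 55, 57, 59, 60, 62, 64)

#: Semitone stacks above the tonic for each chord quality.
QUALITY_INTERVALS = {
    "maj7": (0, 4, 7, 11),
    "min7": (0, 3, 7, 10),
    "dim7": (0, 3, 6, 9),
}

#: Scale degrees (semitones above the key root, mod 12) that carry a major
#: seventh chord in diatonic harmonization: I and IV.
_MAJ7_DEGREES = {0, 5}


class SonifyError(ValueError):
    """Raised for invalid sonification inputs or configuration."""


@dataclass(frozen=True)
class SonifyConfig:
    """Feedback-rendering parameters.

    ``tonic_pitches`` must be exactly ten strictly ascending MIDI pitches,
    one per correlation bin.  ``key_root`` (pitch class 0–11) anchors the
    diatonic maj7/min7 choice for consonant chords; ``consonant_mode``
    may be ``"diatonic"`` or ``"maj7"`` (always major 7th).
    ``chord_dur`` defaults to one TR.  When ``hold_on_invalid`` is set,
    an invalid correlation sample sustains the previous chord instead of
    emitting new feedback.
    """

    tonic_pitches: tuple[int, ...] = DEFAULT_TONICS
    key_root: int = 0
    chord_dur: float | None = None
    velocity: int = 90
    hold_on_invalid: bool = True
    consonant_mode: str = "diatonic"

    def __post_init__(self) -> None:
        pitches = tuple(int(p) for p in self.tonic_pitches)
        if len(pitches) != 10:
            raise SonifyError(f"exactly 10 tonic pitches required, got {len(pitches)}")
        if any(b <= a for a, b in zip(pitches, pitches[1:])):
            raise SonifyError("tonic pitches must be strictly ascending")
        if not 1 <= self.velocity <= 127:
            raise SonifyError(f"velocity must be in 1..127, got {self.velocity}")
        if self.consonant_mode not in ("diatonic", "maj7"):
            raise SonifyError(f"unknown consonant_mode {self.consonant_mode!r}")
        object.__setattr__(self, "tonic_pitches", pitches)


@dataclass(frozen=True)
class ChordEvent:
    """One feedback chord: a tonic bin rendered as a four-note seventh chord."""

    onset: float
    bin: int
    tonic: int
    quality: str
    pitches: tuple[int, int, int, int]
    duration: float

    def __post_init__(self) -> None:
        if self.pitches[0] != self.tonic:
            raise SonifyError("pitches[0] must equal the tonic")
        if any(b <= a for a, b in zip(self.pitches, self.pitches[1:])):
            raise SonifyError("chord pitches must be strictly ascending")


@dataclass(frozen=True)
class CueEvent:
    """A non-chord cue marker: white-noise rest cue or mid-block beep."""

    kind: str  # "noise" | "beep"
    onset: float
    duration: float = 0.0


def corr_to_bin(r: float) -> int:
    """Map a correlation level to its 0.1-wide bin index 0–9.

    ``r`` is clipped to [0, 1] first (negative correlations sound as the
    lowest base note); ``r = 1.0`` belongs to the top bin.
    """
    if not math.isfinite(r):
        raise SonifyError(f"correlation must be finite, got {r}")
    clipped = min(max(r, 0.0), 1.0)
    return min(int(clipped * 10.0), 9)


def _consonant_quality(tonic: int | None, cfg: SonifyConfig) -> str:
    if cfg.consonant_mode == "maj7" or tonic is None:
        return "maj7"
    return "maj7" if (tonic - cfg.key_root) % 12 in _MAJ7_DEGREES else "min7"


def quality_from_delta(
    r_now: float,
    r_prev: float,
    tonic: int | None = None,
    cfg: SonifyConfig | None = None,
) -> str:
    """Chord quality from the correlation change.

    Non-decreasing correlation (ties included) → consonant, either maj7
    or min7 by diatonic harmonization of the tonic in the configured
    key; decreasing correlation → dim7.
    """
    if not (math.isfinite(r_now) and math.isfinite(r_prev)):
        raise SonifyError("correlations must be finite")
    cfg = cfg or SonifyConfig()
    if r_now >= r_prev:
        return _consonant_quality(tonic, cfg)
    return "dim7"


def chord_pitches(tonic: int, quality: str) -> tuple[int, int, int, int]:
    """Four ascending pitches of a seventh chord rooted at ``tonic``."""
    if quality not in QUALITY_INTERVALS:
        raise SonifyError(f"unknown chord quality {quality!r}")
    intervals = QUALITY_INTERVALS[quality]
    if tonic < 0 or tonic + intervals[-1] > 127:
        raise SonifyError(f"chord at tonic {tonic} leaves MIDI pitch range 0-127")
    return tuple(tonic + i for i in intervals)


def _make_chord(r: float, r_prev: float, onset: float, dur: float, cfg: SonifyConfig) -> ChordEvent:
    b = corr_to_bin(r)
    tonic = cfg.tonic_pitches[b]
    quality = quality_from_delta(r, r_prev, tonic=tonic, cfg=cfg)
    return ChordEvent(onset=onset, bin=b, tonic=tonic, quality=quality,
                      pitches=chord_pitches(tonic, quality), duration=dur)


def render_run(
    trace: CorrTrace,
    schedule: RunSchedule,
    cfg: SonifyConfig | None = None,
) -> tuple[list[ChordEvent], list[CueEvent]]:
    """Render the per-TR feedback stream for one run.

    Emits one chord per imagery-labelled sample (duration one TR unless
    configured), a white-noise cue marker per contiguous rest segment,
    and a beep marker at each imagery-block midpoint.  The first imagery
    sample of a block is compared against its own correlation, so every
    block opens consonant.  Invalid correlation samples either sustain
    the previous chord (``hold_on_invalid``, default) or emit a bin-0
    consonant chord.
    """
    cfg = cfg or SonifyConfig()
    if len(trace) != schedule.n_samples:
        raise SonifyError(
            f"trace length {len(trace)} != schedule n_samples {schedule.n_samples}"
        )
    labels = labels_per_sample(schedule)
    tr = schedule.tr
    dur = cfg.chord_dur if cfg.chord_dur is not None else tr

    chords: list[ChordEvent] = []
    cues: list[CueEvent] = [CueEvent("beep", t) for t in beep_times(schedule)]

    prev_r: float | None = None  # last displayed correlation within the block
    prev_chord: ChordEvent | None = None
    in_imagery = False
    rest_start: float | None = None
    for i in range(schedule.n_samples):
        t = i * tr
        if labels[i] != "imagery":
            if rest_start is None:
                rest_start = t
            in_imagery = False
            continue
        if rest_start is not None:
            cues.append(CueEvent("noise", rest_start, duration=t - rest_start))
            rest_start = None
        if not in_imagery:
            prev_r, prev_chord = None, None  # new block: reset the delta reference
            in_imagery = True
        r = trace.r[i]
        if trace.valid[i] and math.isfinite(r):
            chord = _make_chord(r, r if prev_r is None else prev_r, t, dur, cfg)
            prev_r = float(r)
        elif cfg.hold_on_invalid and prev_chord is not None:
            chord = ChordEvent(onset=t, bin=prev_chord.bin, tonic=prev_chord.tonic,
                               quality=prev_chord.quality, pitches=prev_chord.pitches,
                               duration=dur)
        else:
            chord = _make_chord(0.0, 0.0, t, dur, cfg)
        chords.append(chord)
        prev_chord = chord
    if rest_start is not None:
        cues.append(CueEvent("noise", rest_start,
                             duration=schedule.n_samples * tr - rest_start))
    cues.sort(key=lambda c: c.onset)
    return chords, cues


def sham_trace(
    n_samples: int,
    seed: int = 0,
    smoothness: float = 0.8,
    tr: float = 1.5,
    window: int = 8,
) -> CorrTrace:
    """Seeded random feedback for sham runs, shaped like a CorrTrace.

    A smoothed random walk on [0, 1] with Gaussian steps of SD
    ``0.5 * (1 - smoothness)``, reflecting at the bounds, so successive
    feedback values drift plausibly instead of jumping; ``smoothness=0``
    degenerates to i.i.d. uniform draws.  The trace is a pure function
    of the seed — independent of any brain signal by construction.
    """
    if n_samples < 1:
        raise SonifyError(f"n_samples must be >= 1, got {n_samples}")
    if not 0.0 <= smoothness <= 1.0:
        raise SonifyError(f"smoothness must be in [0, 1], got {smoothness}")
    rng = np.random.default_rng(seed)
    if smoothness == 0.0:
        r = rng.uniform(0.0, 1.0, size=n_samples)
    else:
        step_sd = 0.5 * (1.0 - smoothness)
        # start value drawn before the steps so that a truncated run consumes
        # an identical RNG prefix (causality of the sham stream)
        x = rng.uniform(0.0, 1.0)
        steps = rng.normal(0.0, step_sd, size=n_samples)
        r = np.empty(n_samples)
        for i in range(n_samples):
            x += steps[i]
            # reflect into [0, 1]
            x = abs(x)
            if x > 1.0:
                x = 2.0 - x
            x = min(max(x, 0.0), 1.0)
            r[i] = x
    from .connectivity import fisher_z

    return CorrTrace(r=r, z=fisher_z(r), valid=np.ones(n_samples, dtype=bool),
                     window=window, tr=tr)


def write_midi(
    chords: list[ChordEvent],
    cues: list[CueEvent],
    path,
    cfg: SonifyConfig | None = None,
    tempo_us: int = midi.DEFAULT_TEMPO_US,
) -> None:
    """Serialize a rendered run as a format-0 Standard MIDI File.

    Each chord becomes four note-on/note-off pairs at the configured
    velocity; cue markers become text meta events (``cue:noise``,
    ``cue:beep``).
    """
    cfg = cfg or SonifyConfig()
    notes = [
        midi.MidiNote(
            onset_ticks=midi.seconds_to_ticks(c.onset, tempo_us),
            duration_ticks=max(
                1,
                midi.seconds_to_ticks(c.onset + c.duration, tempo_us)
                - midi.seconds_to_ticks(c.onset, tempo_us),
            ),
            pitch=p,
            velocity=cfg.velocity,
        )
        for c in chords
        for p in c.pitches
    ]
    texts = [
        midi.MidiText(midi.seconds_to_ticks(c.onset, tempo_us), f"cue:{c.kind}")
        for c in cues
    ]
    midi.write_smf(notes, texts, path, tempo_us=tempo_us)


def events_to_frame(chords: list[ChordEvent], mode: str = "active") -> pd.DataFrame:
    """Chord log as a table: one row per emitted chord."""
    return pd.DataFrame(
        {
            "time_s": [c.onset for c in chords],
            "bin": [c.bin for c in chords],
            "tonic": [c.tonic for c in chords],
            "quality": [c.quality for c in chords],
            "duration_s": [c.duration for c in chords],
            "mode": mode,
        }
    )
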