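"""Block-design task schedules for localizer and neurofeedback runs.

A functional run is an ordered sequence of non-overlapping condition
blocks (rest, motor imagery, music listening, white noise, pleasantness
report) on a continuous time axis, sampled every TR.  The localizer run
interleaves all five conditions; the neurofeedback run alternates rest
and imagery, with a beep cue halfway through each imagery block telling
the participant to wind the imagined movement down.

Schedules serialize to and from BIDS-style ``events.tsv`` tables
(columns ``onset``, ``duration``, ``trial_type``; seconds, tab-separated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "ConditionBlock",
    "RunSchedule",
    "build_localizer_schedule",
    "build_nf_schedule",
    "beep_times",
    "labels_per_sample",
    "truncate_schedule",
    "schedule_to_events",
    "events_to_schedule",
    "write_events_tsv",
    "read_events_tsv",
]

#: Recognized condition labels.
CONDITIONS = ("rest", "imagery", "music", "noise", "report")

#: Default repetition time in seconds.
DEFAULT_TR = 1.5

#: Localizer trial structure: (label, duration in seconds), in order.
LOCALIZER_TRIAL = (
    ("rest", 6.0),
    ("imagery", 10.0),
    ("music", 10.0),
    ("noise", 10.0),
    ("report", 6.0),
)


class ParadigmError(ValueError):
    """Raised when a schedule or its parameters are invalid."""


@dataclass(frozen=True)
class ConditionBlock:
    """One condition block: a label over ``[onset, onset + duration)`` seconds."""

    label: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.label not in CONDITIONS:
            raise ParadigmError(
                f"unknown condition label {self.label!r}; expected one of {CONDITIONS}"
            )
        if self.onset < 0:
            raise ParadigmError(f"block onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ParadigmError(f"block duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        """End of the block in seconds (exclusive)."""
        return self.onset + self.duration


@dataclass(frozen=True)
class RunSchedule:
    """An ordered, non-overlapping block list plus the sampling grid.

    Parameters
    ----------
    blocks
        Condition blocks sorted by onset; adjacent blocks may abut but
        never overlap.
    run_kind
        ``"localizer"`` or ``"neurofeedback"``.
    tr
        Repetition time (seconds per sample), > 0.
    n_samples
        Number of acquired samples; ``n_samples * tr`` covers the last
        block offset.
    """

    blocks: tuple[ConditionBlock, ...]
    run_kind: str
    tr: float = DEFAULT_TR
    n_samples: int = field(default=0)

    def __post_init__(self) -> None:
        if self.run_kind not in ("localizer", "neurofeedback"):
            raise ParadigmError(f"unknown run_kind {self.run_kind!r}")
        if self.tr <= 0:
            raise ParadigmError(f"tr must be > 0, got {self.tr}")
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.onset < prev.onset:
                raise ParadigmError("blocks must be sorted by onset")
            if cur.onset < prev.offset - 1e-9:
                raise ParadigmError(
                    f"blocks overlap: {prev.label} [{prev.onset}, {prev.offset}) and "
                    f"{cur.label} starting at {cur.onset}"
                )
        if self.n_samples == 0 and blocks:
            # default grid: just covers the last block offset
            end = blocks[-1].offset
            object.__setattr__(self, "n_samples", int(np.ceil(end / self.tr - 1e-9)))
        if blocks and self.n_samples * self.tr < blocks[-1].offset - 1e-9:
            raise ParadigmError(
                f"n_samples * tr = {self.n_samples * self.tr} does not cover the "
                f"last block offset {blocks[-1].offset}"
            )

    @property
    def duration(self) -> float:
        """Total scheduled time in seconds (last block offset, or 0)."""
        return self.blocks[-1].offset if self.blocks else 0.0

    def blocks_of(self, label: str) -> tuple[ConditionBlock, ...]:
        return tuple(b for b in self.blocks if b.label == label)


def _grid_duration(duration: float, tr: float, what: str) -> float:
    """Round a block duration down to the TR grid, warning if it moved."""
    n = np.floor(duration / tr + 1e-9)
    snapped = float(n * tr)
    if abs(snapped - duration) > 1e-9:
        warnings.warn(
            f"{what} duration {duration} s is not a multiple of tr={tr} s; "
            f"rounding down to {snapped} s",
            stacklevel=3,
        )
    return snapped


def build_localizer_schedule(
    n_trials: int = 6,
    tr: float = DEFAULT_TR,
    inter_trial_pad: float = 0.0,
) -> RunSchedule:
    """Build the localizer schedule: per trial, rest (6 s), imagery (10 s),
    music (10 s), noise (10 s), report (6 s), abutting.

    ``inter_trial_pad`` inserts unlabelled (rest-sampled) seconds between
    trials; the default 0 reproduces the printed block durations exactly,
    252 s for six trials.
    """
    if not isinstance(n_trials, (int, np.integer)) or n_trials < 1:
        raise ParadigmError(f"n_trials must be a positive integer, got {n_trials}")
    if tr <= 0:
        raise ParadigmError(f"tr must be > 0, got {tr}")
    if inter_trial_pad < 0:
        raise ParadigmError("inter_trial_pad must be >= 0")
    blocks: list[ConditionBlock] = []
    t = 0.0
    for trial in range(n_trials):
        for label, dur in LOCALIZER_TRIAL:
            blocks.append(ConditionBlock(label, t, dur))
            t += dur
        if trial < n_trials - 1:
            t += inter_trial_pad
    return RunSchedule(tuple(blocks), "localizer", tr=tr)


def build_nf_schedule(
    n_trials: int = 4,
    imagery_s: float = 30.0,
    rest_s: float = 30.0,
    tr: float = DEFAULT_TR,
) -> RunSchedule:
    """Build a neurofeedback schedule: alternating rest / motor-imagery
    blocks, beginning with rest, one (rest, imagery) pair per trial.

    Block durations that do not sit on the TR grid are rounded down with
    a warning so that every block boundary falls on a sample boundary.
    """
    if not isinstance(n_trials, (int, np.integer)) or n_trials < 1:
        raise ParadigmError(f"n_trials must be a positive integer, got {n_trials}")
    if tr <= 0:
        raise ParadigmError(f"tr must be > 0, got {tr}")
    if imagery_s <= 0 or rest_s <= 0:
        raise ParadigmError("imagery_s and rest_s must be > 0")
    imagery_s = _grid_duration(imagery_s, tr, "imagery block")
    rest_s = _grid_duration(rest_s, tr, "rest block")
    if imagery_s <= 0 or rest_s <= 0:
        raise ParadigmError("block duration rounds to zero on the TR grid")
    blocks: list[ConditionBlock] = []
    t = 0.0
    for _ in range(n_trials):
        blocks.append(ConditionBlock("rest", t, rest_s))
        t += rest_s
        blocks.append(ConditionBlock("imagery", t, imagery_s))
        t += imagery_s
    return RunSchedule(tuple(blocks), "neurofeedback", tr=tr)


def beep_times(schedule: RunSchedule) -> list[float]:
    """Beep cue timestamps: the midpoint of every imagery block of a
    neurofeedback schedule.  Localizer schedules have no beep → empty list.
    """
    if schedule.run_kind != "neurofeedback":
        return []
    return [b.onset + b.duration / 2.0 for b in schedule.blocks_of("imagery")]


def labels_per_sample(schedule: RunSchedule) -> np.ndarray:
    """Per-sample condition labels (length ``n_samples``).

    Sample ``i`` (acquired at time ``i * tr``) takes the label of the block
    whose half-open interval ``[onset, onset + duration)`` contains that
    time; boundary samples belong to the later block.  Samples outside all
    blocks are labelled ``rest``.
    """
    labels = np.full(schedule.n_samples, "rest", dtype=object)
    t = np.arange(schedule.n_samples) * schedule.tr
    for b in schedule.blocks:
        labels[(t >= b.onset - 1e-9) & (t < b.offset - 1e-9)] = b.label
    return labels


def truncate_schedule(schedule: RunSchedule, n_samples: int) -> RunSchedule:
    """Clip a schedule to its first ``n_samples`` samples.

    Blocks past the cut are dropped; a block straddling it is shortened
    so the per-sample labels of the result are exactly the prefix of the
    full schedule's labels.
    """
    if not 1 <= n_samples <= schedule.n_samples:
        raise ParadigmError(
            f"n_samples must be in 1..{schedule.n_samples}, got {n_samples}"
        )
    end = n_samples * schedule.tr
    blocks = []
    for b in schedule.blocks:
        if b.onset >= end - 1e-9:
            break
        blocks.append(
            ConditionBlock(b.label, b.onset, min(b.duration, end - b.onset))
        )
    return RunSchedule(tuple(blocks), schedule.run_kind, tr=schedule.tr, n_samples=n_samples)


def block_sample_bounds(schedule: RunSchedule, block: ConditionBlock) -> tuple[int, int]:
    """Half-open sample-index range ``[start, stop)`` covered by ``block``."""
    start = int(np.ceil(block.onset / schedule.tr - 1e-9))
    stop = int(np.ceil(block.offset / schedule.tr - 1e-9))
    return start, min(stop, schedule.n_samples)


# ---------------------------------------------------------------------------
# BIDS-style events serialization


def schedule_to_events(schedule: RunSchedule) -> pd.DataFrame:
    """Schedule → BIDS-style events table (onset, duration, trial_type)."""
    return pd.DataFrame(
        {
            "onset": [b.onset for b in schedule.blocks],
            "duration": [b.duration for b in schedule.blocks],
            "trial_type": [b.label for b in schedule.blocks],
        }
    )


def events_to_schedule(
    events: pd.DataFrame,
    run_kind: str,
    tr: float = DEFAULT_TR,
    n_samples: int = 0,
) -> RunSchedule:
    """Events table → schedule; the grid (tr, n_samples) is supplied by the
    caller since events.tsv does not carry it."""
    blocks = tuple(
        ConditionBlock(str(row.trial_type), float(row.onset), float(row.duration))
        for row in events.itertuples()
    )
    return RunSchedule(blocks, run_kind, tr=tr, n_samples=n_samples)


def write_events_tsv(schedule: RunSchedule, path) -> None:
    schedule_to_events(schedule).to_csv(path, sep="\t", index=False)


def read_events_tsv(path, run_kind: str, tr: float = DEFAULT_TR, n_samples: int = 0) -> RunSchedule:
    return events_to_schedule(pd.read_csv(path, sep="\t"), run_kind, tr=tr, n_samples=n_samples)
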