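"""Closed-loop neurofeedback simulation at per-TR cadence.

``run_loop`` replays a (simulated or file-loaded) two-ROI run through
the full feedback chain: causal sliding-window correlation → active or
sham displayed value → chord rendering.  The loop is an offline
per-sample pipeline, not a wall-clock process: real-time behaviour is
modelled logically as one update per TR, and strict causality (the
chord at sample t depends only on samples ≤ t) is a tested invariant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import CorrTrace, RoiPair, sliding_corr
from .paradigm import (
    RunSchedule,
    labels_per_sample,
    read_events_tsv,
    write_events_tsv,
)
from .sonify import ChordEvent, CueEvent, SonifyConfig, render_run, sham_trace

__all__ = ["RunRecord", "run_loop", "assign_crossover"]

MODES = ("active", "sham")


class LoopError(ValueError):
    """Raised for invalid closed-loop configuration."""


@dataclass(frozen=True)
class RunRecord:
    """Complete per-TR log of one closed-loop run.

    ``rows`` has one row per sample: raw metric (``r_raw``), displayed
    metric (``r_displayed`` — equal to ``r_raw`` in active mode, the
    sham trace in sham mode), the emitted chord's bin and quality (empty
    outside imagery), and validity.  ``seeds`` records the signal and
    sham seeds; ``config_hash`` fingerprints the sonification config.
    """

    mode: str
    rows: pd.DataFrame
    schedule: RunSchedule
    seeds: dict[str, int | None]
    config_hash: str
    window: int = 8
    chords: tuple[ChordEvent, ...] = ()
    cues: tuple[CueEvent, ...] = ()

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, out_dir) -> None:
        """Serialize as ``record.tsv`` + ``events.tsv`` + JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "record.tsv", sep="\t", index=False)
        write_events_tsv(self.schedule, out / "events.tsv")
        sidecar = {
            "mode": self.mode,
            "seeds": self.seeds,
            "config_hash": self.config_hash,
            "window": self.window,
            "tr": self.schedule.tr,
            "n_samples": self.schedule.n_samples,
            "run_kind": self.schedule.run_kind,
        }
        (out / "record.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, out_dir) -> "RunRecord":
        out = Path(out_dir)
        sidecar = json.loads((out / "record.json").read_text())
        schedule = read_events_tsv(
            out / "events.tsv",
            run_kind=sidecar["run_kind"],
            tr=sidecar["tr"],
            n_samples=sidecar["n_samples"],
        )
        rows = pd.read_csv(out / "record.tsv", sep="\t", keep_default_na=False,
                           na_values=[""])
        return cls(
            mode=sidecar["mode"],
            rows=rows,
            schedule=schedule,
            seeds=sidecar["seeds"],
            config_hash=sidecar["config_hash"],
            window=sidecar.get("window", 8),
        )

    def displayed_trace(self, window: int | None = None) -> CorrTrace:
        """Rebuild the displayed CorrTrace from the logged rows (replay)."""
        from .connectivity import fisher_z

        r = self.rows["r_displayed"].to_numpy(dtype=float)
        valid = self.rows["valid"].to_numpy().astype(bool)
        z = np.full(r.size, np.nan)
        z[valid] = fisher_z(np.clip(r[valid], -1, 1))
        return CorrTrace(r=r, z=z, valid=valid,
                         window=self.window if window is None else window,
                         tr=self.schedule.tr)


def _config_hash(window: int, cfg: SonifyConfig) -> str:
    payload = {
        "window": window,
        "tonic_pitches": cfg.tonic_pitches,
        "key_root": cfg.key_root,
        "chord_dur": cfg.chord_dur,
        "velocity": cfg.velocity,
        "hold_on_invalid": cfg.hold_on_invalid,
        "consonant_mode": cfg.consonant_mode,
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_loop(
    source,
    schedule: RunSchedule | None = None,
    mode: str = "active",
    window: int = 8,
    sonify_cfg: SonifyConfig | None = None,
    sham_seed: int | None = None,
    sham_smoothness: float = 0.8,
) -> RunRecord:
    """Run the closed loop over a signal source.

    ``source`` is a :class:`RoiPair` (with ``schedule`` given) or a
    simulated run carrying its own schedule.  In active mode the
    displayed metric is the windowed correlation itself; in sham mode it
    is a seeded random trace independent of the signal, presented with
    the same timing (feedback exists only during imagery blocks either
    way).
    """
    if mode not in MODES:
        raise LoopError(f"mode must be one of {MODES}, got {mode!r}")
    signal_seed: int | None = None
    if hasattr(source, "pair"):  # simulated run
        pair: RoiPair = source.pair
        schedule = schedule or source.schedule
        signal_seed = getattr(source, "seed", None)
    else:
        pair = source
        if schedule is None:
            raise LoopError("a schedule is required when the source is a bare RoiPair")
    if len(pair) != schedule.n_samples:
        raise LoopError(
            f"source length {len(pair)} != schedule n_samples {schedule.n_samples}"
        )
    cfg = sonify_cfg or SonifyConfig()

    raw = sliding_corr(pair, window=window)
    if mode == "sham":
        if sham_seed is None:
            raise LoopError("sham mode requires a sham_seed")
        displayed = sham_trace(
            schedule.n_samples, seed=sham_seed, smoothness=sham_smoothness,
            tr=schedule.tr, window=window,
        )
    else:
        displayed = raw

    chords, cues = render_run(displayed, schedule, cfg)
    chord_at = {round(c.onset / schedule.tr): c for c in chords}
    labels = labels_per_sample(schedule)
    n = schedule.n_samples
    rows = pd.DataFrame(
        {
            "sample": np.arange(n),
            "time_s": np.arange(n) * schedule.tr,
            "condition": labels,
            "left": pair.left,
            "right": pair.right,
            "r_raw": raw.r,
            "r_displayed": displayed.r,
            "valid": displayed.valid.astype(int),
            "bin": [chord_at[i].bin if i in chord_at else -1 for i in range(n)],
            "quality": [chord_at[i].quality if i in chord_at else "" for i in range(n)],
        }
    )
    return RunRecord(
        mode=mode,
        rows=rows,
        schedule=schedule,
        seeds={"signal": signal_seed, "sham": sham_seed},
        config_hash=_config_hash(window, cfg),
        window=window,
        chords=tuple(chords),
        cues=tuple(cues),
    )


def assign_crossover(participant_index: int, n_runs: int = 4) -> tuple[str, ...]:
    """Crossover run-order assignment.

    Even participant indices receive sham feedback in the first half of
    their runs and active feedback in the second half; odd indices the
    reverse — so half the cohort is sham-first.
    """
    if n_runs % 2 != 0 or n_runs < 2:
        raise LoopError(f"n_runs must be a positive even number, got {n_runs}")
    half = n_runs // 2
    if participant_index % 2 == 0:
        return ("sham",) * half + ("active",) * half
    return ("active",) * half + ("sham",) * half
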