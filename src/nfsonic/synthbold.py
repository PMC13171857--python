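"""Synthetic two-ROI BOLD generator with condition-dependent coupling.

Stands in for the scanner: each run is a pair of premotor-cortex BOLD
series whose *neural-level* interhemispheric correlation is set per
condition.  The generative model per ROI i ∈ {L, R} is

    n_i(t) = a(t) * ( sqrt(rho(t)) * s(t) + sqrt(1 - rho(t)) * e_i(t) )
    y_i(t) = (h * n_i)(t) + drift_slope * t + AR(1) noise of SD noise_sd

with s, e_L, e_R independent unit-variance white Gaussian sequences, so
corr(n_L, n_R) = rho(t) exactly in expectation, h the canonical
double-gamma hemodynamic response (unit peak), and rho(t), a(t) driven
by the block schedule.  Everything is seeded and bit-reproducible.

Cohorts follow the study's crossover layout: four neurofeedback runs per
subject, two active and two sham, sham-first for even subject indices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .connectivity import RoiPair
from .paradigm import RunSchedule, labels_per_sample

__all__ = [
    "HrfParams",
    "SimConfig",
    "SimulatedRun",
    "Cohort",
    "CohortRun",
    "hrf_kernel",
    "simulate_pair",
    "simulate_cohort",
    "simulate_ratings",
]

#: Default per-condition neural correlation: strong coupling during motor
#: imagery, weak spontaneous coupling otherwise.
DEFAULT_COUPLING = {
    "rest": 0.1,
    "imagery": 0.7,
    "music": 0.2,
    "noise": 0.1,
    "report": 0.1,
}

#: Default neural amplitude per condition.  Constant across conditions:
#: the modulated quantity is the coupling, not the activation level.
DEFAULT_AMPLITUDE = {c: 1.0 for c in DEFAULT_COUPLING}


class SimulationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response shape (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated run.

    ``coupling_map`` gives the target neural correlation rho per condition
    (in [0, 1]); ``amp_map`` the neural amplitude.  ``noise_sd`` is the
    stationary SD of the AR(1) measurement noise; ``ar1`` its lag-1
    coefficient.  ``drift_slope`` adds a linear scanner drift (units per
    sample).  ``taper_second_half`` halves the imagery amplitude after
    the mid-block beep, mirroring the instructed slow-down of the
    imagined movement.
    """

    coupling_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    amp_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDE))
    noise_sd: float = 0.5
    ar1: float = 0.3
    drift_slope: float = 0.01
    hrf_params: HrfParams = field(default_factory=HrfParams)
    taper_second_half: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for label, rho in self.coupling_map.items():
            if not 0.0 <= rho <= 1.0:
                raise SimulationError(f"coupling for {label!r} must be in [0, 1], got {rho}")
        if self.noise_sd < 0:
            raise SimulationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.ar1 < 1.0:
            raise SimulationError(f"ar1 must be in [0, 1), got {self.ar1}")

    def hash(self) -> str:
        payload = {
            "coupling_map": self.coupling_map,
            "amp_map": self.amp_map,
            "noise_sd": self.noise_sd,
            "ar1": self.ar1,
            "drift_slope": self.drift_slope,
            "hrf_params": vars(self.hrf_params),
            "taper_second_half": self.taper_second_half,
            "seed": self.seed,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SimulatedRun:
    """One synthetic run: the ROI pair, its schedule, and the generating
    per-sample coupling (``truth``)."""

    pair: RoiPair
    schedule: RunSchedule
    truth: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if len(self.pair) != self.schedule.n_samples or self.truth.size != len(self.pair):
            raise SimulationError("pair, truth and schedule lengths disagree")


def hrf_kernel(tr: float, params: HrfParams | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr``, peak normalized to 1.

    Positive early lobe peaking near 5–6 s, small late undershoot; the
    kernel covers ``params.length`` seconds (default 32 s).
    """
    if tr <= 0:
        raise SimulationError(f"tr must be > 0, got {tr}")
    p = params or HrfParams()
    t = np.arange(0, p.length + tr / 2, tr)
    peak = gamma_dist.pdf(t, p.peak_delay / p.peak_disp, scale=p.peak_disp)
    under = gamma_dist.pdf(t, p.undershoot_delay / p.undershoot_disp, scale=p.undershoot_disp)
    h = peak - p.undershoot_ratio * under
    return h / h.max()


def _rho_amp_per_sample(schedule: RunSchedule, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    labels = labels_per_sample(schedule)
    present = {str(l) for l in labels}
    missing = sorted((present - set(cfg.coupling_map)) | (present - set(cfg.amp_map)))
    if missing:
        raise SimulationError(f"no coupling/amplitude configured for label(s): {missing}")
    rho = np.array([cfg.coupling_map[str(l)] for l in labels])
    amp = np.array([cfg.amp_map[str(l)] for l in labels], dtype=float)
    if cfg.taper_second_half:
        t = np.arange(schedule.n_samples) * schedule.tr
        for block in schedule.blocks_of("imagery"):
            beep = block.onset + block.duration / 2.0
            amp[(t >= beep) & (t < block.offset)] *= 0.5
    return rho, amp


def simulate_pair(schedule: RunSchedule, cfg: SimConfig) -> SimulatedRun:
    """Simulate one two-ROI run under ``cfg`` on the given schedule."""
    n = schedule.n_samples
    if n < 2:
        raise SimulationError("schedule must cover at least 2 samples")
    rho, amp = _rho_amp_per_sample(schedule, cfg)

    rng = np.random.default_rng(cfg.seed)
    shared = rng.standard_normal(n)
    e_left = rng.standard_normal(n)
    e_right = rng.standard_normal(n)
    w_shared = np.sqrt(rho)
    w_priv = np.sqrt(1.0 - rho)
    neural_l = amp * (w_shared * shared + w_priv * e_left)
    neural_r = amp * (w_shared * shared + w_priv * e_right)

    h = hrf_kernel(schedule.tr, cfg.hrf_params)
    bold_l = np.convolve(neural_l, h)[:n]
    bold_r = np.convolve(neural_r, h)[:n]

    drift = cfg.drift_slope * np.arange(n)
    bold_l = bold_l + drift + _ar1_noise(rng, n, cfg)
    bold_r = bold_r + drift + _ar1_noise(rng, n, cfg)

    pair = RoiPair(bold_l, bold_r, tr=schedule.tr)
    return SimulatedRun(pair=pair, schedule=schedule, truth=rho, seed=cfg.seed)


def _ar1_noise(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    if cfg.noise_sd == 0:
        return np.zeros(n)
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - cfg.ar1**2)
    eps = rng.standard_normal(n) * innov_sd
    noise = np.empty(n)
    noise[0] = rng.standard_normal() * cfg.noise_sd  # stationary start
    for k in range(1, n):
        noise[k] = cfg.ar1 * noise[k - 1] + eps[k]
    return noise


@dataclass(frozen=True)
class CohortRun:
    subject: int
    run_index: int
    mode: str  # "active" | "sham"
    sim: SimulatedRun


@dataclass(frozen=True)
class Cohort:
    runs: tuple[CohortRun, ...]
    seed: int

    def subjects(self) -> list[int]:
        return sorted({r.subject for r in self.runs})

    def runs_of(self, subject: int) -> list[CohortRun]:
        return [r for r in self.runs if r.subject == subject]


def simulate_cohort(
    n_subjects: int,
    runs_per_subject: int = 4,
    cfg_active: SimConfig | None = None,
    cfg_sham_behavior: SimConfig | None = None,
    seed: int = 0,
    schedule: RunSchedule | None = None,
    coupling_jitter_sd: float = 0.05,
) -> Cohort:
    """Simulate a crossover cohort of neurofeedback runs.

    Even subject indices get sham feedback in the first half of their
    runs, odd indices in the second half.  ``cfg_active`` parameterizes
    the brain behaviour during active runs, ``cfg_sham_behavior`` during
    sham runs (defaults to ``cfg_active``: random feedback does not, by
    itself, change the generative brain model).  Per-subject imagery and
    rest coupling are jittered around the configured values by a
    truncated Gaussian of SD ``coupling_jitter_sd``.
    """
    from .nfloop import assign_crossover  # local import: no module cycle at import time

    if n_subjects < 2:
        raise SimulationError(f"n_subjects must be >= 2, got {n_subjects}")
    cfg_active = cfg_active or SimConfig()
    cfg_sham = cfg_sham_behavior or cfg_active
    from .paradigm import build_nf_schedule

    schedule = schedule or build_nf_schedule()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(n_subjects)
    runs: list[CohortRun] = []
    for subj in range(n_subjects):
        modes = assign_crossover(subj, runs_per_subject)
        subj_rng = np.random.default_rng(subject_seeds[subj])
        run_seeds = subj_rng.integers(0, 2**31 - 1, size=runs_per_subject)
        jitter = {}
        for label in ("imagery", "rest"):
            jitter[label] = float(subj_rng.normal(0.0, coupling_jitter_sd))
        for run_idx, mode in enumerate(modes):
            base = cfg_active if mode == "active" else cfg_sham
            coupling = dict(base.coupling_map)
            for label, dj in jitter.items():
                if label in coupling:
                    coupling[label] = float(np.clip(coupling[label] + dj, 0.0, 1.0))
            cfg_run = replace(base, coupling_map=coupling, seed=int(run_seeds[run_idx]))
            runs.append(
                CohortRun(
                    subject=subj,
                    run_index=run_idx,
                    mode=mode,
                    sim=simulate_pair(schedule, cfg_run),
                )
            )
    return Cohort(runs=tuple(runs), seed=seed)


def simulate_ratings(
    n_consonant: int,
    n_dissonant: int,
    shift: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic chord-pleasantness ratings on the 1–5 scale.

    Consonant chords draw from a discretized Gaussian centred at 4,
    dissonant chords from the same distribution shifted down by
    ``shift`` rating units; both are rounded and clamped to {1..5}.
    ``shift=0`` puts both groups on the same distribution.
    """
    if shift < 0:
        raise SimulationError(f"shift must be >= 0, got {shift}")
    rng = np.random.default_rng(seed)

    def draw(n: int, center: float) -> np.ndarray:
        raw = np.rint(rng.normal(center, 0.8, size=n))
        return np.clip(raw, 1, 5).astype(int)

    return draw(n_consonant, 4.0), draw(n_dissonant, 4.0 - shift)
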