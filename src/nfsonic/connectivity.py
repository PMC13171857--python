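"""Sliding-window interhemispheric correlation — the online feedback metric.

The feedback source is the Pearson correlation between the left and
right premotor-cortex BOLD series over a short causal window (default 8
samples) ending at the current sample.  Correlations are mapped to
Fisher z = artanh(r) for statistics; raw r feeds the sonifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import RunSchedule, block_sample_bounds

__all__ = [
    "RoiPair",
    "CorrTrace",
    "sliding_corr",
    "fisher_z",
    "aggregate_by_condition",
    "blockwise_timecourse",
]

#: Correlations are clipped to +/- this bound before artanh so that z stays
#: finite for degenerate (perfectly correlated) windows.
R_MAX = 0.999999

#: Relative variance below which a window counts as constant → invalid sample.
_VAR_TOL = 1e-12


class ConnectivityError(ValueError):
    """Raised for invalid inputs to the connectivity computations."""


@dataclass(frozen=True)
class RoiPair:
    """Two synchronous single-ROI BOLD series (left / right hemisphere)."""

    left: np.ndarray
    right: np.ndarray
    tr: float = 1.5

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=float)
        right = np.asarray(self.right, dtype=float)
        if left.ndim != 1 or right.ndim != 1:
            raise ConnectivityError("ROI series must be one-dimensional")
        if left.shape != right.shape:
            raise ConnectivityError(
                f"left and right series differ in length: {left.size} vs {right.size}"
            )
        if left.size < 2:
            raise ConnectivityError("ROI series must contain at least 2 samples")
        if self.tr <= 0:
            raise ConnectivityError(f"tr must be > 0, got {self.tr}")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    def __len__(self) -> int:
        return self.left.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"left": self.left, "right": self.right})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, tr: float = 1.5) -> "RoiPair":
        df = pd.read_csv(path, sep="\t")
        return cls(df["left"].to_numpy(), df["right"].to_numpy(), tr=tr)


@dataclass(frozen=True)
class CorrTrace:
    """Per-sample windowed correlation with validity bookkeeping.

    ``r[t]`` is the Pearson correlation of the ``window`` most recent
    samples ending at (and including) ``t``.  Samples before the first
    full window, and samples whose window has zero variance in either
    channel, are invalid (``r`` is NaN there).
    """

    r: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    window: int
    tr: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))

    def __len__(self) -> int:
        return self.r.size

    @property
    def valid_from(self) -> int:
        """Index of the first sample with a full window."""
        return self.window - 1

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.tr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": np.arange(len(self)),
                "time_s": self.time_s,
                "r": self.r,
                "z": self.z,
                "valid": self.valid.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, window: int = 8, tr: float = 1.5) -> "CorrTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            df["r"].to_numpy(),
            df["z"].to_numpy(),
            df["valid"].to_numpy().astype(bool),
            window=window,
            tr=tr,
        )


def sliding_corr(pair: RoiPair, window: int = 8) -> CorrTrace:
    """Causal sliding-window Pearson correlation of the two ROI series.

    Each valid sample ``t`` holds the correlation of samples
    ``t-window+1 .. t``; a real-time system can only look backwards.
    Zero-variance windows are flagged invalid rather than propagating
    NaN or an arbitrary value — the correlation is undefined there.
    """
    if window < 3:
        raise ConnectivityError(f"window must be >= 3 samples, got {window}")
    n = len(pair)
    if window > n:
        raise ConnectivityError(f"window ({window}) exceeds series length ({n})")

    wins_l = np.lib.stride_tricks.sliding_window_view(pair.left, window)
    wins_r = np.lib.stride_tricks.sliding_window_view(pair.right, window)
    dl = wins_l - wins_l.mean(axis=1, keepdims=True)
    dr = wins_r - wins_r.mean(axis=1, keepdims=True)
    ss_l = np.einsum("ij,ij->i", dl, dl)
    ss_r = np.einsum("ij,ij->i", dr, dr)
    cov = np.einsum("ij,ij->i", dl, dr)

    scale_l = np.einsum("ij,ij->i", wins_l, wins_l)
    scale_r = np.einsum("ij,ij->i", wins_r, wins_r)
    ok = (ss_l > _VAR_TOL * np.maximum(scale_l, 1.0)) & (
        ss_r > _VAR_TOL * np.maximum(scale_r, 1.0)
    )

    r_win = np.full(n - window + 1, np.nan)
    np.divide(cov, np.sqrt(ss_l * ss_r), out=r_win, where=ok)
    np.clip(r_win, -1.0, 1.0, out=r_win)

    r = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    r[window - 1 :] = r_win
    valid[window - 1 :] = ok
    z = np.full(n, np.nan)
    z[valid] = fisher_z(r[valid])
    return CorrTrace(r=r, z=z, valid=valid, window=window, tr=pair.tr)


def fisher_z(r):
    """Fisher variance-stabilizing transform z = artanh(r).

    ``r`` is clipped to ±0.999999 first so perfectly correlated windows
    map to a large finite z instead of infinity.  Accepts scalars or
    arrays; odd and strictly increasing on (-1, 1).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ConnectivityError("fisher_z requires |r| <= 1")
    z = np.arctanh(np.clip(arr, -R_MAX, R_MAX))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def aggregate_by_condition(
    trace: CorrTrace,
    labels: np.ndarray,
    stat: str = "mean",
) -> dict[str, float]:
    """Per-condition summary of the Fisher-z trace over valid samples.

    Conditions without a single valid sample are absent from the result.
    """
    labels = np.asarray(labels)
    if labels.size != len(trace):
        raise ConnectivityError(
            f"labels length {labels.size} != trace length {len(trace)}"
        )
    if stat not in ("mean", "median"):
        raise ConnectivityError(f"stat must be 'mean' or 'median', got {stat!r}")
    reduce = np.mean if stat == "mean" else np.median
    out: dict[str, float] = {}
    for label in pd.unique(labels):
        sel = trace.valid & (labels == label)
        if sel.any():
            out[str(label)] = float(reduce(trace.z[sel]))
    return out


def blockwise_timecourse(
    traces: list[CorrTrace],
    schedule: RunSchedule,
    conditions: tuple[str, ...] = ("imagery", "rest"),
) -> dict[str, np.ndarray]:
    """Block-locked mean Fisher-z time course per condition.

    For each condition, all its blocks (across all traces) are aligned on
    within-block sample offset and averaged over valid samples, giving one
    mean-z value per offset — the ingredients of a per-timepoint paired
    comparison between imagery and rest.  All blocks of a condition must
    have equal duration.
    """
    if not traces:
        raise ConnectivityError("at least one trace is required")
    for t in traces:
        if len(t) != schedule.n_samples:
            raise ConnectivityError(
                f"trace length {len(t)} != schedule n_samples {schedule.n_samples}"
            )
    out: dict[str, np.ndarray] = {}
    for label in conditions:
        blocks = schedule.blocks_of(label)
        if not blocks:
            continue
        spans = [block_sample_bounds(schedule, b) for b in blocks]
        lengths = {stop - start for start, stop in spans}
        if len(lengths) != 1:
            raise ConnectivityError(
                f"{label} blocks have unequal durations: {sorted(lengths)} samples"
            )
        length = lengths.pop()
        stacked = np.full((len(traces) * len(spans), length), np.nan)
        row = 0
        for trace in traces:
            for start, stop in spans:
                seg = trace.z[start:stop].copy()
                seg[~trace.valid[start:stop]] = np.nan
                stacked[row] = seg
                row += 1
        with np.errstate(invalid="ignore"):
            out[label] = np.nanmean(stacked, axis=0)
    return out
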