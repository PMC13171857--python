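"""Offline statistical battery for neurofeedback modulation success.

The success metric is the mean Fisher-z windowed correlation during
motor-imagery blocks, compared against rest with one-sided paired
Wilcoxon signed-rank tests (Bonferroni-corrected for the active and
sham comparisons).  The battery also covers chord-pleasantness ratings
(Mann-Whitney U), pre/post mood subscales (two-sided paired Wilcoxon
with Holm-Bonferroni across subscales and effect size r = |z|/sqrt(n)),
per-timepoint block-locked comparisons, and the behaviour–success
association (ordinary least squares + Pearson r).

Small samples use exact enumeration of the permutation null (all sign
flips / group assignments, mid-ranks for ties); larger samples fall
back to the normal approximation with continuity and tie corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import aggregate_by_condition
from .paradigm import labels_per_sample

__all__ = [
    "TestResult",
    "GroupStats",
    "success_metric",
    "cohort_success",
    "modulation_tests",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "holm_bonferroni",
    "timepoint_tests",
    "pre_post_compare",
    "associate",
]

#: Largest sample size for which the exact permutation null is enumerated.
EXACT_N_MAX = 12


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


class UndefinedTestError(StatsError):
    """Raised when a test is undefined (e.g. all paired differences zero)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    n: int
    method: str


@dataclass(frozen=True)
class GroupStats:
    """One corrected group comparison, Fig-8 style."""

    comparison: str
    test: str
    statistic: float
    p_raw: float
    p_corrected: float
    alternative: str
    n_comparisons: int
    median_a: float
    median_b: float


# ---------------------------------------------------------------------------
# success metric


def success_metric(records_by_subject: dict, window: int = 8) -> pd.DataFrame:
    """Per-subject mean Fisher z for active-NF imagery, sham-NF imagery, rest.

    ``records_by_subject`` maps subject id → list of RunRecords.  The raw
    (brain-derived) metric is aggregated over valid samples; rest pools
    all runs.  Subjects missing an active or a sham run are excluded
    with a warning.
    """
    rows = []
    for subject, records in records_by_subject.items():
        modes = {rec.mode for rec in records}
        if not {"active", "sham"} <= modes:
            warnings.warn(f"subject {subject!r} lacks an active or sham run; excluded")
            continue
        per_cond: dict[str, list[float]] = {"active": [], "sham": [], "rest": []}
        for rec in records:
            from .connectivity import CorrTrace, fisher_z

            r = rec.rows["r_raw"].to_numpy(dtype=float)
            valid = np.isfinite(r)
            z = np.full(r.size, np.nan)
            z[valid] = fisher_z(np.clip(r[valid], -1, 1))
            trace = CorrTrace(r=r, z=z, valid=valid, window=window, tr=rec.schedule.tr)
            agg = aggregate_by_condition(trace, labels_per_sample(rec.schedule))
            if "imagery" in agg:
                per_cond[rec.mode].append(agg["imagery"])
            if "rest" in agg:
                per_cond["rest"].append(agg["rest"])
        if not (per_cond["active"] and per_cond["sham"] and per_cond["rest"]):
            warnings.warn(f"subject {subject!r} has no valid samples in a condition; excluded")
            continue
        rows.append(
            {
                "subject": subject,
                "active_z": float(np.mean(per_cond["active"])),
                "sham_z": float(np.mean(per_cond["sham"])),
                "rest_z": float(np.mean(per_cond["rest"])),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "active_z", "sham_z", "rest_z"])


def cohort_success(cohort, window: int = 8) -> pd.DataFrame:
    """Success metric straight from a simulated cohort (no chord rendering).

    Computes the windowed correlation of each run's ROI pair and
    aggregates mean imagery z (split by active/sham run mode) and mean
    rest z per subject.  Equivalent to running the full loop and calling
    :func:`success_metric`, minus the sonification overhead.
    """
    from .connectivity import sliding_corr

    rows = []
    for subject in cohort.subjects():
        per_cond: dict[str, list[float]] = {"active": [], "sham": [], "rest": []}
        for crun in cohort.runs_of(subject):
            trace = sliding_corr(crun.sim.pair, window=window)
            agg = aggregate_by_condition(trace, labels_per_sample(crun.sim.schedule))
            if "imagery" in agg:
                per_cond[crun.mode].append(agg["imagery"])
            if "rest" in agg:
                per_cond["rest"].append(agg["rest"])
        rows.append(
            {
                "subject": subject,
                "active_z": float(np.mean(per_cond["active"])),
                "sham_z": float(np.mean(per_cond["sham"])),
                "rest_z": float(np.mean(per_cond["rest"])),
            }
        )
    return pd.DataFrame(rows)


def modulation_tests(
    success: pd.DataFrame,
    alternative: str = "greater",
    n_comparisons: int = 2,
) -> list[GroupStats]:
    """Active-vs-rest and sham-vs-rest one-sided Wilcoxon tests,
    Bonferroni-corrected for the two comparisons."""
    out = []
    for col, name in (("active_z", "active NF vs rest"), ("sham_z", "sham NF vs rest")):
        res = wilcoxon_signed_rank(
            success[col].to_numpy(), success["rest_z"].to_numpy(), alternative=alternative
        )
        out.append(
            GroupStats(
                comparison=name,
                test="wilcoxon_signed_rank",
                statistic=res.statistic,
                p_raw=res.p_value,
                p_corrected=min(1.0, res.p_value * n_comparisons),
                alternative=alternative,
                n_comparisons=n_comparisons,
                median_a=float(success[col].median()),
                median_b=float(success["rest_z"].median()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# nonparametric primitives


def wilcoxon_signed_rank(
    x,
    y=None,
    alternative: str = "two-sided",
) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment, the
    common statistical-package default).  For n ≤ 12 remaining pairs the
    exact permutation null (all 2^n sign flips, mid-ranks for tied
    magnitudes) is enumerated; above that, the normal approximation with
    continuity and tie corrections is used.  The statistic is the sum of
    the ranks of positive differences (one-sided) or the smaller signed
    rank sum (two-sided), matching common reporting.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    if n <= EXACT_N_MAX:
        method = sps.PermutationMethod(n_resamples=2**EXACT_N_MAX + 1, rng=0)
        name = "wilcoxon-exact"
    else:
        method = "approx"
        name = "wilcoxon-normal"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, alternative=alternative, method=method, correction=True)
    return TestResult(float(res.statistic), float(res.pvalue), alternative, n, name)


def wilcoxon_effect_size_r(x, y, n_override: int | None = None) -> float:
    """Effect size r = |z| / sqrt(n) from the normal approximation of the
    paired Wilcoxon statistic (zeros dropped, tie-corrected variance)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        raise UndefinedTestError("degenerate variance in signed-rank statistic")
    z = (w_plus - mean) / np.sqrt(var)
    return float(abs(z) / np.sqrt(n_override if n_override is not None else n))


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test for two independent samples.

    For combined sample size ≤ 12 the exact permutation null (all group
    assignments, mid-ranks for ties) is enumerated; above that, the
    normal approximation with continuity and tie corrections is used.
    The statistic is U of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    if a.size + b.size <= EXACT_N_MAX:
        method = sps.PermutationMethod(n_resamples=2**EXACT_N_MAX + 1, rng=0)
        name = "mannwhitney-exact"
    else:
        method = "asymptotic"
        name = "mannwhitney-normal"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      a.size + b.size, name)


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down adjustment.

    Returns (adjusted p values, reject flags at ``alpha``); adjusted
    values are monotone in the raw ordering and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


# ---------------------------------------------------------------------------
# composite analyses


def timepoint_tests(
    active_tc: np.ndarray,
    rest_tc: np.ndarray,
    alternative: str = "two-sided",
    correction: int = 2,
) -> pd.DataFrame:
    """Paired Wilcoxon at each within-block sample offset.

    ``active_tc`` and ``rest_tc`` are (subjects × offsets) block-locked
    mean-z time courses.  Each offset is tested across subjects and the
    p value Bonferroni-multiplied by ``correction`` (default 2: the
    imagery-vs-rest comparison is run for active and sham runs).
    Offsets where every subject shows a zero difference are reported
    with p = 1 rather than erroring.
    """
    active_tc = np.atleast_2d(np.asarray(active_tc, dtype=float))
    rest_tc = np.atleast_2d(np.asarray(rest_tc, dtype=float))
    if active_tc.shape != rest_tc.shape:
        raise StatsError("time courses must have identical (subjects, offsets) shape")
    n_subjects, n_offsets = active_tc.shape
    if n_subjects < 5:
        raise UndefinedTestError(
            f"at least 5 subjects required for the per-timepoint test, got {n_subjects}"
        )
    rows = []
    for j in range(n_offsets):
        try:
            res = wilcoxon_signed_rank(active_tc[:, j], rest_tc[:, j], alternative)
            w, p = res.statistic, res.p_value
        except UndefinedTestError:
            w, p = np.nan, 1.0
        rows.append(
            {
                "offset": j,
                "W": w,
                "p_raw": p,
                "p_corrected": min(1.0, p * correction),
            }
        )
    return pd.DataFrame(rows)


def pre_post_compare(
    before: pd.DataFrame,
    after: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pre/post comparison per subscale (e.g. mood questionnaire scores).

    ``before`` and ``after`` are (subjects × subscales) tables with the
    same columns.  Each subscale gets a two-sided paired Wilcoxon;
    p values are Holm-Bonferroni-adjusted across subscales and the
    effect size r = |z|/sqrt(n) is reported alongside the medians.
    """
    if list(before.columns) != list(after.columns) or len(before) != len(after):
        raise StatsError("before/after tables must share columns and row count")
    results = []
    for col in before.columns:
        x = before[col].to_numpy(dtype=float)
        y = after[col].to_numpy(dtype=float)
        res = wilcoxon_signed_rank(x, y, alternative="two-sided")
        results.append(
            {
                "subscale": col,
                "median_before": float(np.median(x)),
                "median_after": float(np.median(y)),
                "W": res.statistic,
                "p_raw": res.p_value,
                "effect_r": wilcoxon_effect_size_r(x, y),
                "n": res.n,
            }
        )
    table = pd.DataFrame(results)
    p_adj, reject = holm_bonferroni(table["p_raw"].to_numpy(), alpha=alpha)
    table["p_corrected"] = p_adj
    table["reject"] = reject
    return table


def associate(behavior, success) -> TestResult | tuple:
    """Behaviour–success association: OLS line and Pearson correlation.

    Returns (slope, intercept, pearson_r, p_value).  Requires n ≥ 3 and
    a non-constant predictor.
    """
    x = np.asarray(behavior, dtype=float)
    y = np.asarray(success, dtype=float)
    if x.size != y.size:
        raise StatsError("behavior and success must be paired")
    if x.size < 3:
        raise StatsError(f"at least 3 observations required, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("constant predictor: association is undefined")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)
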