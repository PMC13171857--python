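"""Nonparametric battery: exact enumeration oracles and composite analyses."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from nfsonic import stats
from nfsonic.stats import (
    StatsError,
    UndefinedTestError,
    associate,
    holm_bonferroni,
    mann_whitney_u,
    pre_post_compare,
    timepoint_tests,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent enumeration oracles (never call the implementation under test)


def wilcoxon_enum(d, alternative):
    """Exact signed-rank p by enumerating all sign patterns (mid-ranks)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = np.array(
        [np.dot(signs, ranks) for signs in product((0.0, 1.0), repeat=n)]
    )
    total = dist.size
    p_ge = np.sum(dist >= w_obs - 1e-9) / total
    p_le = np.sum(dist <= w_obs + 1e-9) / total
    if alternative == "greater":
        return w_obs, p_ge
    if alternative == "less":
        return w_obs, p_le
    return w_obs, min(1.0, 2.0 * min(p_ge, p_le))


def mwu_enum(a, b, alternative):
    """Exact Mann-Whitney p by enumerating all group assignments (mid-ranks)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = a.size
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    dist = []
    for idx in combinations(range(pooled.size), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        dist.append(u)
    dist = np.array(dist)
    total = dist.size
    p_ge = np.sum(dist >= u_obs - 1e-9) / total
    p_le = np.sum(dist <= u_obs + 1e-9) / total
    if alternative == "greater":
        return u_obs, p_ge
    if alternative == "less":
        return u_obs, p_le
    return u_obs, min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxonSignedRank:
    def test_all_positive_ranks(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 6.0), np.zeros(5), "greater")
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(1.0 / 32.0, abs=1e-12)

    def test_identical_samples_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 7.0])  # last pair ties
        res = wilcoxon_signed_rank(x, y, "greater")
        assert res.n == 5
        assert res.p_value == pytest.approx(1.0 / 32.0, abs=1e-12)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(100)
        for _ in range(25):
            n = int(rng.integers(5, 11))
            d = rng.choice([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5], size=n).astype(float)
            res = wilcoxon_signed_rank(d, np.zeros(n), alternative)
            _, p_exp = wilcoxon_enum(d, alternative)
            assert res.p_value == pytest.approx(p_exp, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(101)
        x = rng.normal(0.5, 1.0, size=30)
        res = wilcoxon_signed_rank(x, np.zeros(30), "greater")
        assert res.method == "wilcoxon-normal"
        assert 0.0 < res.p_value < 1.0


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_u_half(self):
        res = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.statistic == 4.0**2 / 2

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1, 2])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(102)
        for _ in range(25):
            na = int(rng.integers(3, 6))
            nb = int(rng.integers(3, 6))
            a = rng.integers(1, 6, size=na).astype(float)  # ties likely
            b = rng.integers(1, 6, size=nb).astype(float)
            res = mann_whitney_u(a, b, alternative)
            u_exp, p_exp = mwu_enum(a, b, alternative)
            assert res.statistic == pytest.approx(u_exp)
            assert res.p_value == pytest.approx(p_exp, abs=1e-12)

    def test_ratings_comparison_detects_shift(self):
        from nfsonic.synthbold import simulate_ratings

        cons, diss = simulate_ratings(40, 40, shift=2.0, seed=3)
        res = mann_whitney_u(cons, diss, "greater")
        assert res.p_value < 0.001


class TestHolmBonferroni:
    def test_step_down_adjustment(self):
        p_adj, reject = holm_bonferroni([0.01, 0.04], alpha=0.05)
        np.testing.assert_allclose(p_adj, [0.02, 0.04])
        assert reject.all()

    def test_running_max_blocks_both(self):
        p_adj, reject = holm_bonferroni([0.03, 0.04], alpha=0.05)
        np.testing.assert_allclose(p_adj, [0.06, 0.06])
        assert not reject.any()

    def test_single_p_unchanged(self):
        p_adj, _ = holm_bonferroni([0.2])
        assert p_adj[0] == pytest.approx(0.2)

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(103)
        p = rng.uniform(0, 1, size=12)
        p_adj, _ = holm_bonferroni(p)
        assert np.all(p_adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-15)

    def test_rejects_invalid_p(self):
        with pytest.raises(StatsError):
            holm_bonferroni([0.5, 1.2])


class TestSuccessMetric:
    def test_constant_correlation_closed_form(self, nf_schedule):
        from nfsonic.nfloop import RunRecord
        from nfsonic.paradigm import labels_per_sample

        n = nf_schedule.n_samples
        labels = labels_per_sample(nf_schedule)
        r = np.where(labels == "imagery", 0.8, 0.0)

        def record(mode):
            rows = pd.DataFrame({"r_raw": r, "r_displayed": r, "valid": 1})
            return RunRecord(mode=mode, rows=rows, schedule=nf_schedule,
                             seeds={}, config_hash="x")

        table = stats.success_metric({"s1": [record("active"), record("sham")]})
        row = table.iloc[0]
        assert row.active_z == pytest.approx(np.arctanh(0.8), abs=1e-9)
        assert row.sham_z == pytest.approx(np.arctanh(0.8), abs=1e-9)
        assert row.rest_z == pytest.approx(0.0, abs=1e-9)

    def test_subject_missing_condition_excluded(self, nf_schedule):
        from nfsonic.nfloop import RunRecord

        rows = pd.DataFrame(
            {"r_raw": np.full(nf_schedule.n_samples, 0.5), "valid": 1}
        )
        rec = RunRecord(mode="active", rows=rows, schedule=nf_schedule,
                        seeds={}, config_hash="x")
        with pytest.warns(UserWarning, match="excluded"):
            table = stats.success_metric({"s1": [rec]})
        assert table.empty

    def test_cohort_success_recovers_coupling_ordering(self):
        from nfsonic.synthbold import simulate_cohort

        cohort = simulate_cohort(6, seed=17)
        table = stats.cohort_success(cohort)
        assert len(table) == 6
        # strong imagery coupling shows at the cohort level; individual
        # subjects may fluctuate
        assert table["active_z"].mean() > table["rest_z"].mean()
        assert (table["active_z"] > table["rest_z"]).sum() >= 4


class TestTimepointTests:
    def test_equal_timecourses_nothing_significant(self):
        tc = np.tile(np.linspace(0, 1, 10), (8, 1))
        out = timepoint_tests(tc, tc.copy())
        assert (out["p_corrected"] == 1.0).all()

    def test_uniform_shift_every_offset(self):
        rng = np.random.default_rng(104)
        rest = rng.normal(size=(10, 6))
        out = timepoint_tests(rest + 1.0, rest, alternative="greater")
        assert len(out) == 6
        assert (out["W"] == 55.0).all()
        np.testing.assert_allclose(out["p_raw"], 1.0 / 1024.0, atol=1e-12)
        np.testing.assert_allclose(out["p_corrected"], 2.0 / 1024.0, atol=1e-12)

    def test_too_few_subjects_rejected(self):
        tc = np.zeros((4, 5))
        with pytest.raises(UndefinedTestError):
            timepoint_tests(tc, tc + 1)


class TestPrePost:
    def test_identical_scores_undefined(self):
        df = pd.DataFrame({"tension": [3, 4, 5, 3, 2, 4]})
        with pytest.raises(UndefinedTestError):
            pre_post_compare(df, df.copy())

    def test_shifted_subscale_detected_with_effect_size(self):
        rng = np.random.default_rng(105)
        n = 22
        before = pd.DataFrame(
            {
                "tension": rng.integers(2, 6, n),
                "vigor": rng.integers(8, 15, n),
            }
        )
        after = before.copy()
        after["tension"] = np.clip(before["tension"] - 3 + rng.integers(0, 2, n), 0, None)
        after["vigor"] = before["vigor"] + rng.integers(-1, 2, n)  # unshifted, jittered
        out = pre_post_compare(before, after)
        tension = out[out["subscale"] == "tension"].iloc[0]
        assert tension["p_corrected"] < 0.05
        assert 0.0 < tension["effect_r"] <= 1.0
        assert tension["median_after"] < tension["median_before"]
        assert len(out) == 2

    def test_detection_rate_across_seeds(self):
        """A -3 median tension shift in n=22 is detected in >=90% of seeds."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            before = pd.DataFrame({"tension": rng.integers(2, 6, 22)})
            after = before - 3 + rng.integers(0, 2, (22, 1))
            out = pre_post_compare(before, after)
            hits += out["p_corrected"].iloc[0] < 0.05
        assert hits >= 0.9 * reps


class TestAssociate:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r, p = associate(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_independent_data_low_correlation(self):
        rng = np.random.default_rng(106)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        _, _, r, _ = associate(x, y)
        assert abs(r) < 0.3

    def test_r_squared_identity(self):
        rng = np.random.default_rng(107)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        slope, intercept, r, _ = associate(x, y)
        resid = y - (slope * x + intercept)
        r2 = 1 - resid.var() / y.var()
        assert r**2 == pytest.approx(r2, abs=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(StatsError):
            associate(np.ones(10), np.arange(10.0))


class TestModulationTests:
    def test_fig8_style_output(self):
        from nfsonic.synthbold import simulate_cohort

        cohort = simulate_cohort(12, seed=23)
        table = stats.cohort_success(cohort)
        results = stats.modulation_tests(table)
        assert [g.comparison for g in results] == [
            "active NF vs rest", "sham NF vs rest",
        ]
        for g in results:
            assert g.p_corrected == pytest.approx(min(1.0, g.p_raw * 2))
            assert g.p_corrected >= g.p_raw
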