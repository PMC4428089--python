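"""Exact Mann-Whitney, Spearman, and the cohort analysis battery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from math import comb
from scipy import stats as sps

from lungmorph import (analysis_battery, describe, exact_mann_whitney_p,
                       mann_whitney, simulate_cohort, spearman, u_statistic)
from lungmorph.phantom import CohortSimSpec
from lungmorph.pft import derive_columns
from oracles import (mann_whitney_p_bruteforce, mann_whitney_u_bruteforce,
                     spearman_p_bruteforce, spearman_r_bruteforce)


class TestMannWhitney:
    def test_small_example_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_stat == 0.0
        assert res.p_value == pytest.approx(2 / 6)
        assert "exact" in res.method

    def test_identical_samples_p_one(self):
        assert exact_mann_whitney_p([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    def test_complete_separation_10_vs_6(self):
        x = list(range(10))
        y = list(range(100, 106))
        res = mann_whitney(x, y)
        assert res.u_stat == 0.0
        assert res.p_value == pytest.approx(2 / comb(16, 10))
        assert "exact" in res.method

    def test_u_complementarity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
            assert u_statistic(x, y) + u_statistic(y, x) == pytest.approx(
                len(x) * len(y))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_exact_p_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 7))
        # draw from a small integer support so ties are frequent
        x = rng.integers(0, 5, size=n1).astype(float)
        y = rng.integers(0, 5, size=n2).astype(float)
        assert comb(n1 + n2, n1) <= 5000
        assert u_statistic(x, y) == pytest.approx(
            mann_whitney_u_bruteforce(x, y))
        assert exact_mann_whitney_p(x, y) == pytest.approx(
            mann_whitney_p_bruteforce(x, y))

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            ours = exact_mann_whitney_p(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_approximate_path_reasonable(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=60)
        y = rng.normal(0.2, 1, size=55)
        res = mann_whitney(x, y, mode="approximate")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert "approximation" in res.method
        assert res.p_value == pytest.approx(ref, rel=1e-6)

    def test_mode_auto_switches_on_cap(self):
        x = list(range(10))
        y = list(range(6))
        assert "exact" in mann_whitney(x, y, mode="auto").method
        assert "approximation" in mann_whitney(x, y, mode="auto",
                                               exact_cap=100).method

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_null_pvalues_not_anticonservative(self):
        # under the null the exact test's rejection rate cannot exceed
        # alpha (discreteness makes it conservative)
        rng = np.random.default_rng(3)
        rej = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=7)
            y = rng.normal(size=5)
            rej += exact_mann_whitney_p(x, y) < 0.05
        assert rej / reps <= 0.07


class TestSpearman:
    def test_monotone_extremes(self):
        up = spearman([1, 2, 3, 4, 5], [10, 20, 25, 30, 41])
        assert up.r == pytest.approx(1.0)
        down = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert down.r == pytest.approx(-1.0)

    def test_worked_example_with_permutation_p(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)
        assert res.p_value == pytest.approx(10 / 24)
        assert "permutation" in res.method

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_rank_then_pearson_and_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            x[0], y[0] = -1.0, -1.0  # avoid zero rank variance
        res = spearman(x, y)
        assert res.r == pytest.approx(spearman_r_bruteforce(x, y))
        assert res.p_value == pytest.approx(spearman_p_bruteforce(x, y))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_invariant_under_strictly_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = spearman(x, y)
        trans = spearman(np.exp(x), 3.0 * y ** 3 + y)
        assert trans.r == pytest.approx(base.r)
        assert trans.p_value == pytest.approx(base.p_value)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        res = spearman(x, x + rng.normal(0, 0.5, size=12))
        assert "t approximation" in res.method
        ref = sps.spearmanr(x, x + 0).pvalue  # sanity only: r path below
        assert -1 <= res.r <= 1

    def test_agrees_with_scipy_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestDescribe:
    def test_odd_and_even_medians(self):
        assert describe([1, 2, 3]) == (2.0, (1.0, 3.0))
        assert describe([1, 2, 3, 4]) == (2.5, (1.0, 4.0))

    def test_generator_median_recovered(self):
        sim = simulate_cohort(CohortSimSpec(n_patients=400, n_controls=2,
                                            seed=6), make_phantoms=False)
        med, _ = describe(sim.table[sim.table.group == "patient"]
                          ["cc_ratio_true"])
        assert med == pytest.approx(1.35, abs=0.03)


class TestAnalysisBattery:
    @staticmethod
    def _joined(noise_sd=2.0, seed=0):
        sim = simulate_cohort(CohortSimSpec(noise_sd=noise_sd, seed=seed),
                              make_phantoms=False)
        df = derive_columns(sim.table)
        return df.rename(columns={"cc_ratio_true": "cc_ratio"}).assign(
            ap_ratio=lambda d: d["ap_expansion"],
            lr_ratio=lambda d: d["lr_expansion"])

    def test_exact_path_taken_for_pilot_sized_cohort(self):
        report = analysis_battery(self._joined())
        cc = report.comparison("cc_ratio")
        assert "exact" in cc.method
        assert cc.n1 == 10 and cc.n2 == 6

    def test_correlations_are_patient_only(self):
        report = analysis_battery(self._joined())
        corr = report.correlation("cc_ratio", "fvc_supine_pct")
        assert corr.n == 10
        sens = analysis_battery(self._joined(),
                                include_controls_in_correlations=True)
        assert sens.correlation("cc_ratio", "fvc_supine_pct").n == 16

    def test_separated_groups_detected(self):
        report = analysis_battery(self._joined())
        assert report.comparison("cc_ratio").p_value < 0.05
        assert "cc_ratio" in report.significant()

    def test_strong_link_gives_high_rank_correlation(self):
        report = analysis_battery(self._joined(noise_sd=0.5))
        assert abs(report.correlation("cc_ratio", "delta_fvc_pct").r) >= 0.8
        assert report.correlation("cc_ratio", "fvc_supine_pct").r >= 0.8

    def test_missing_group_rejected(self):
        df = self._joined()
        with pytest.raises(ValueError):
            analysis_battery(df[df.group == "patient"])
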