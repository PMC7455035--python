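"""Normality-gated comparisons, nested ANOVA, correlation, power, behavior."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import capiflow as cf
from capiflow import stats as S


class TestCompareGroups:
    def test_identical_samples_no_difference(self):
        a = cf.GroupSample("A", [1.0, 2.0, 3.0, 4.0])
        b = cf.GroupSample("B", [1.0, 2.0, 3.0, 4.0])
        r = cf.compare_groups(a, b, sensitivity=False)
        if r.test_used == "t-test":
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value > 0.9

    def test_gate_selects_mann_whitney_on_skewed_data(self):
        rng = np.random.default_rng(1)
        picked = 0
        n_seeds = 200
        for _ in range(n_seeds):
            a = cf.GroupSample("A", rng.lognormal(0, 2.0, 25))
            b = cf.GroupSample("B", rng.lognormal(0, 2.0, 25))
            r = cf.compare_groups(a, b, sensitivity=False)
            picked += r.test_used == "mann-whitney"
            assert (r.test_used == "t-test") == all(
                p >= 0.05 for p in r.normality_p.values()
            )
        assert picked / n_seeds >= 0.95

    def test_type_one_error_nominal(self):
        """Type-I error of the full gated procedure at n = 4 per group."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_seeds = 1000
        for _ in range(n_seeds):
            a = cf.GroupSample("A", rng.normal(0, 1, 4))
            b = cf.GroupSample("B", rng.normal(0, 1, 4))
            rejections += cf.compare_groups(a, b, sensitivity=False).p_value < 0.05
        assert rejections / n_seeds == pytest.approx(0.05, abs=0.015)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            cf.compare_groups(cf.GroupSample("A", [1.0, 2.0]),
                              cf.GroupSample("B", [1.0, 2.0, 3.0]))


class TestNestedAnova:
    def _balanced_toy(self):
        return pd.DataFrame({
            "group": ["A"] * 6 + ["B"] * 6,
            "mouse": ["a1"] * 3 + ["a2"] * 3 + ["b1"] * 3 + ["b2"] * 3,
            "value": [1.0, 2, 3, 2, 3, 4, 3, 4, 5, 4, 5, 6],
        })

    def test_hand_worked_f(self):
        """Balanced 2x2x3 toy: SS_group = 12, MS_mouse(group) = 1.5, F = 8."""
        r = cf.nested_anova(self._balanced_toy())
        assert r.statistic == pytest.approx(8.0)
        assert r.df == (1, 2)
        assert r.p_value == pytest.approx(float(sps.f.sf(8.0, 1, 2)))

    def test_reduces_to_mouse_level_t_test(self):
        """In the balanced case F equals t² from the t-test on mouse means."""
        df = self._balanced_toy()
        means = df.groupby(["group", "mouse"])["value"].mean()
        t = sps.ttest_ind(means["A"], means["B"]).statistic
        r = cf.nested_anova(df)
        assert r.statistic == pytest.approx(t ** 2)

    def test_all_equal_values(self):
        df = self._balanced_toy()
        df["value"] = 5.0
        r = cf.nested_anova(df)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_single_mouse_group_rejected(self):
        df = pd.DataFrame({
            "group": ["A", "A", "B", "B", "B", "B"],
            "mouse": ["a1", "a1", "b1", "b1", "b2", "b2"],
            "value": [1.0, 2, 3, 4, 5, 6],
        })
        with pytest.raises(ValueError, match="single unit"):
            cf.nested_anova(df)

    def test_controls_type_one_error_where_naive_fails(self):
        """Under strong mouse effects the nested test holds its level while
        the vessel-level t-test grossly inflates it."""
        rng = np.random.default_rng(7)
        n_seeds = 500
        rej_nested = rej_naive = 0
        for _ in range(n_seeds):
            rows = []
            for g in ("A", "B"):
                for m in range(4):
                    mu = rng.normal(0.0, 1.0)
                    for v in rng.normal(mu, 0.5, 15):
                        rows.append((g, f"{g}{m}", v))
            df = pd.DataFrame(rows, columns=["group", "mouse", "value"])
            rej_nested += cf.nested_anova(df).p_value < 0.05
            a = df.loc[df.group == "A", "value"]
            b = df.loc[df.group == "B", "value"]
            rej_naive += sps.ttest_ind(a, b).pvalue < 0.05
        assert rej_nested / n_seeds == pytest.approx(0.05, abs=0.02)
        assert rej_naive / n_seeds > 0.15


class TestPearsonCorrelation:
    def test_perfect_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r = cf.pearson_correlation(x, 2 * x + 1)
        assert r.r == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)

    def test_hand_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r = cf.pearson_correlation(x, y)
        assert r.r == pytest.approx(num / den)

    def test_null_p_uniform(self):
        """Independent x and y at n = 8: the p-value distribution is uniform."""
        rng = np.random.default_rng(5)
        ps = [
            cf.pearson_correlation(rng.normal(size=8), rng.normal(size=8)).p_value
            for _ in range(1000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            cf.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMinDetectableProportionDiff:
    def test_limit_at_alpha_power(self):
        d = cf.min_detectable_proportion_diff(100, 100, 0.3, alpha=0.05,
                                              power=0.0500001)
        assert d < 1e-3

    def test_monotone_in_n(self):
        d1 = cf.min_detectable_proportion_diff(50, 50, 0.1)
        d2 = cf.min_detectable_proportion_diff(100, 100, 0.1)
        assert d2 < d1

    def test_matches_monte_carlo_power(self):
        """At the returned difference, the simulated two-proportion z-test
        rejects at approximately the target power."""
        n, p0 = 10000, 0.01
        d = cf.min_detectable_proportion_diff(n, n, p0, direction="increase")
        rng = np.random.default_rng(4)
        m = 20000
        x1 = rng.binomial(n, p0 + d, m) / n
        x0 = rng.binomial(n, p0, m) / n
        se = np.sqrt(x1 * (1 - x1) / n + x0 * (1 - x0) / n)
        power = (np.abs(x1 - x0) / np.maximum(se, 1e-12) > 1.959964).mean()
        assert power == pytest.approx(0.80, abs=0.02)

    def test_rejects_bad_baseline(self):
        with pytest.raises(ValueError):
            cf.min_detectable_proportion_diff(10, 10, 0.0)


class TestMinDetectableMeanShift:
    def test_scale_equivariance(self):
        s1 = cf.min_detectable_mean_shift(6, 6, 1.0)
        s3 = cf.min_detectable_mean_shift(6, 6, 3.0)
        assert s3 == pytest.approx(3 * s1)

    def test_vanishes_with_sd(self):
        assert cf.min_detectable_mean_shift(6, 6, 1e-9) < 1e-6

    def test_matches_monte_carlo_power(self):
        shift = cf.min_detectable_mean_shift(4, 4, 1.0)
        rng = np.random.default_rng(3)
        m = 20000
        a = rng.normal(0, 1, (m, 4))
        b = rng.normal(shift, 1, (m, 4))
        power = (sps.ttest_ind(a, b, axis=1).pvalue < 0.05).mean()
        assert power == pytest.approx(0.80, abs=0.02)

    def test_percent_of_reference(self):
        shift, pct = cf.min_detectable_mean_shift(8, 8, 2.0, ref_mean=10.0)
        assert pct == pytest.approx(10 * shift)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(ValueError):
            cf.min_detectable_mean_shift(4, 4, 0.0)


class TestBehaviorScores:
    def test_preference_examples(self):
        assert cf.preference_score(5.0, 5.0) == 0.5
        assert cf.preference_score(3.0, 0.0) == 1.0
        assert cf.preference_score(12.0, 4.0) == 0.75

    def test_preference_undefined(self):
        with pytest.warns(UserWarning):
            assert math.isnan(cf.preference_score(0.0, 0.0))

    def test_alternation_examples(self):
        assert cf.spontaneous_alternation(8, 10) == 1.0
        assert cf.spontaneous_alternation(0, 10) == 0.0

    def test_alternation_bound_enforced(self):
        with pytest.raises(ValueError, match="entries - 2"):
            cf.spontaneous_alternation(9, 10)

    def test_alternation_undefined_below_three_entries(self):
        with pytest.warns(UserWarning):
            assert math.isnan(cf.spontaneous_alternation(0, 2))

    def test_random_walk_alternation_near_half(self):
        """Uniform choice among the two other arms alternates a triad with
        probability 1/2, so the mean score is ~0.5."""
        rng = np.random.default_rng(9)
        scores = []
        for _ in range(10000):
            arms = [rng.integers(3)]
            for _ in range(19):
                nxt = (arms[-1] + rng.integers(1, 3)) % 3
                arms.append(int(nxt))
            triads = sum(
                len({arms[i], arms[i + 1], arms[i + 2]}) == 3
                for i in range(len(arms) - 2)
            )
            scores.append(cf.spontaneous_alternation(triads, len(arms)))
        assert np.mean(scores) == pytest.approx(0.5, abs=0.02)

    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4), st.floats(0.1, 1e3))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_preference_scale_invariant_and_bounded(self, t1, t2, scale):
        if t1 + t2 == 0.0:
            return
        p = cf.preference_score(t1, t2)
        assert 0.0 <= p <= 1.0
        assert cf.preference_score(t1 * scale, t2 * scale) == pytest.approx(p)
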