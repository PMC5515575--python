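"""Kaplan-Meier, median lifespan, percent change and the log-rank test."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lifespans import (
    EstimationError,
    km_estimate,
    logrank_test,
    median_lifespan,
    percent_change,
)


class TestKaplanMeier:
    def test_single_death(self):
        curve = km_estimate([100.0])
        assert curve.survival_at(99.9) == 1.0
        assert curve.survival_at(100.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        ages = [2.0, 4.0, 4.0, 6.0]
        curve = km_estimate(ages)
        np.testing.assert_allclose(curve.survival, [0.75, 0.25, 0.0])
        np.testing.assert_array_equal(curve.times, [2.0, 4.0, 6.0])
        # against the empirical survival function at arbitrary points
        for t in (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0):
            emp = np.mean(np.asarray(ages) > t)
            assert curve.survival_at(t) == pytest.approx(emp)

    def test_hand_product_limit_with_censoring(self):
        # deaths {2, 4}, censored {3}: S(2) = 2/3, S(4) = (2/3)*(1-1/1) = 0
        curve = km_estimate([2.0, 3.0, 4.0], events=[True, False, True])
        np.testing.assert_allclose(curve.survival, [2.0 / 3.0, 0.0])

    def test_all_censored_warns_constant_one(self):
        with pytest.warns(UserWarning, match="censored"):
            curve = km_estimate([5.0, 6.0], events=[False, False])
        assert curve.survival_at(10.0) == 1.0

    def test_random_cohort_survival_matches_empirical(self, rng):
        ages = rng.gamma(5.0, 100.0, size=200) + 1.0
        curve = km_estimate(ages)
        grid = np.quantile(ages, [0.1, 0.5, 0.9])
        for t in grid:
            assert curve.survival_at(t) == pytest.approx(np.mean(ages > t))


class TestMedian:
    @pytest.mark.parametrize(
        "ages,expected",
        [
            ([5.0], 5.0),
            ([1.0, 2.0, 3.0], 2.0),
            ([1.0, 2.0, 3.0, 4.0], 2.0),  # first time S hits 0.5 exactly
        ],
    )
    def test_median_convention(self, ages, expected):
        assert median_lifespan(ages) == expected

    def test_median_undefined_under_heavy_censoring(self):
        with pytest.raises(EstimationError, match="median"):
            median_lifespan([1.0, 2.0, 3.0, 4.0], events=[True, False, False, False])

    def test_median_equals_quantile_definition(self, rng):
        """Uncensored KM median = smallest observed age with S(t) <= 1/2."""
        ages = np.round(rng.gamma(6.0, 120.0, size=51)) + 1.0
        med = median_lifespan(ages)
        assert np.mean(ages > med) <= 0.5
        below = ages[ages < med]
        assert all(np.mean(ages > t) > 0.5 for t in below)


class TestPercentChange:
    def test_week1_pooled_arithmetic(self):
        pc = percent_change(1004.0, 839.0)
        assert pc.days_rounded == 165 and pc.percent_rounded == 16

    def test_week1_male_arithmetic(self):
        pc = percent_change(1011.0, 807.0)
        assert pc.days_rounded == 204 and pc.percent_rounded == 20

    def test_no_change_is_zero(self):
        pc = percent_change(850.0, 850.0)
        assert pc.days == 0.0 and pc.percent == 0.0

    def test_nonpositive_reference_rejected(self):
        from lifespans import ParameterError

        with pytest.raises(ParameterError):
            percent_change(0.0, 5.0)


def _exact_permutation_p(ages_a, ages_b):
    """Enumerate the permutation distribution of the log-rank statistic over
    all group relabelings; p = share of relabelings at least as extreme."""
    pooled = np.concatenate([ages_a, ages_b])
    na = len(ages_a)
    observed = logrank_test(ages_a, ages_b).statistic
    count = total = 0
    for idx in itertools.combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        stat = logrank_test(pooled[mask], pooled[~mask]).statistic
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total


class TestLogRank:
    def test_identical_groups_stat_zero(self):
        g = [3.0, 5.0, 8.0]
        res = logrank_test(g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_accumulated_example(self):
        # A={1,2}, B={3,4}: O_A=2, E_A=5/6, V=17/36 -> chi2 = 49/17
        res = logrank_test([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(49.0 / 17.0)
        assert res.observed[0] == 2
        assert res.expected[0] == pytest.approx(5.0 / 6.0)
        assert res.variance == pytest.approx(17.0 / 36.0)

    def test_swapping_groups_invariant(self, rng):
        a, b = rng.gamma(4, 150, 9) + 1, rng.gamma(5, 150, 7) + 1
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_monotone_transform_invariant(self, rng):
        a, b = rng.gamma(4, 150, 8) + 1, rng.gamma(5, 150, 8) + 1
        r1 = logrank_test(a, b)
        r2 = logrank_test(np.sqrt(a), np.sqrt(b))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_zero_variance_warns_p_one(self):
        with pytest.warns(UserWarning, match="variance"):
            res = logrank_test([5.0], [5.0])
        assert res.p_value == 1.0

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines.statistics")
        a, b = rng.gamma(4, 150, 40) + 1, rng.gamma(5, 170, 35) + 1
        ours = logrank_test(a, b)
        ref = lifelines.logrank_test(a, b)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-10)

    def test_small_sample_p_tracks_exact_permutation(self, rng):
        """Chi-square p and the exact permutation p rank instances alike."""
        chi2_p, perm_p = [], []
        for _ in range(8):
            a = np.round(rng.gamma(4.0, 120.0, rng.integers(3, 7))) + 1
            b = np.round(rng.gamma(6.0, 120.0, rng.integers(3, 7))) + 1
            chi2_p.append(logrank_test(a, b).p_value)
            perm_p.append(_exact_permutation_p(a, b))
        rho = stats.spearmanr(chi2_p, perm_p).statistic
        assert rho > 0.85
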