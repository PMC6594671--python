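"""Product-limit estimator and log-rank test, checked by hand, against
lifelines, and against a brute-force permutation oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietsurv import (
    ValidationError,
    km_estimate,
    logrank,
    median_survival,
    pairwise_logrank,
)
from dietsurv.survival import _logrank_core


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at 1 and 3, censored at 2: S=2/3 on [1,3), 0 at 3
        c = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(c.times, [1, 3])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])
        np.testing.assert_array_equal(c.at_risk, [3, 1])
        assert c.survival_at(2.5) == pytest.approx(2 / 3)
        assert c.survival_at(0.5) == 1.0

    def test_all_censored_is_flat_one(self):
        c = km_estimate([5, 10, 15], [0, 0, 0])
        assert len(c.times) == 0
        assert c.survival_at(100) == 1.0

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(50, 200)
        e = rng.integers(0, 2, 200)
        c = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        theirs = np.array([kmf.predict(x) for x in c.times])
        np.testing.assert_allclose(c.survival, theirs, atol=1e-10)

    def test_curve_invariants(self, rng):
        t = rng.exponential(30, 100)
        e = rng.integers(0, 2, 100)
        c = km_estimate(t, e)
        assert (np.diff(c.survival) <= 1e-12).all()
        assert ((c.survival >= 0) & (c.survival <= 1)).all()
        assert (np.diff(c.at_risk) < 0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1, 2], [1, 1])


class TestMedianSurvival:
    def test_first_crossing(self):
        c = km_estimate([25, 30], [1, 1])  # S: 0.5 at 25, 0 at 30
        assert median_survival(c) == 25

    def test_undefined_when_above_half(self):
        c = km_estimate([10, 20, 30, 40, 50], [1, 0, 0, 0, 0])  # S stays at 0.8
        assert median_survival(c) is None

    def test_exponential_closed_form(self, rng):
        lam = np.log(2) / 50  # true median 50
        t = rng.exponential(1 / lam, 5000)
        med = median_survival(km_estimate(t, np.ones(5000, dtype=int)))
        assert 45 <= med <= 55


class TestLogRank:
    def test_identical_groups_give_null(self):
        t = [3.0, 5.0, 7.0, 11.0]
        e = [1, 0, 1, 1]
        res = logrank([(t, e), (t, e)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_observed_minus_expected_sums_to_zero(self, rng):
        groups = [
            (rng.exponential(40, 30), rng.integers(0, 2, 30)),
            (rng.exponential(60, 25), rng.integers(0, 2, 25)),
            (rng.exponential(20, 35), rng.integers(0, 2, 35)),
        ]
        res = logrank(groups)
        assert res.df == 2
        assert (res.observed - res.expected).sum() == pytest.approx(0.0, abs=1e-9)

    def test_matches_lifelines_two_and_three_groups(self, rng):
        stats_mod = pytest.importorskip("lifelines.statistics")
        g = [
            (rng.exponential(40, 40), rng.integers(0, 2, 40)),
            (rng.exponential(25, 35), rng.integers(0, 2, 35)),
            (rng.exponential(55, 30), rng.integers(0, 2, 30)),
        ]
        res2 = logrank(g[:2])
        ll2 = stats_mod.logrank_test(g[0][0], g[1][0], g[0][1], g[1][1])
        assert res2.statistic == pytest.approx(ll2.test_statistic, rel=1e-9)
        assert res2.p_value == pytest.approx(ll2.p_value, rel=1e-9)
        times = np.concatenate([x[0] for x in g])
        events = np.concatenate([x[1] for x in g])
        labels = np.repeat([0, 1, 2], [40, 35, 30])
        ll3 = stats_mod.multivariate_logrank_test(times, labels, events)
        res3 = logrank(g)
        assert res3.statistic == pytest.approx(ll3.test_statistic, rel=1e-9)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError, match="no events"):
            logrank([([1, 2], [0, 0]), ([3, 4], [0, 0])])

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank([([1, 2], [1, 1])])

    @given(st.sampled_from([np.exp, np.sqrt, lambda x: 10 * x + 3]))
    @settings(max_examples=10, deadline=None)
    def test_invariant_to_monotone_time_transform(self, f):
        rng = np.random.default_rng(3)
        t1, e1 = rng.exponential(30, 25), rng.integers(0, 2, 25)
        t2, e2 = rng.exponential(50, 25), rng.integers(0, 2, 25)
        r0 = logrank([(t1, e1), (t2, e2)])
        r1 = logrank([(f(t1), e1), (f(t2), e2)])
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-9)

    def test_permutation_p_matches_exact_enumeration(self):
        """On 8 subjects the 4-vs-4 relabeling null can be enumerated
        exactly; the resampled permutation p must agree within its own
        Monte-Carlo error."""
        times = np.array([3.0, 5.0, 8.0, 9.0, 12.0, 13.0, 20.0, 25.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        obs_labels = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        obs_stat, _, _ = _logrank_core(times, events, obs_labels, 2)
        hits = total = 0
        for combo in itertools.combinations(range(8), 4):
            labels = np.ones(8, dtype=int)
            labels[list(combo)] = 0
            stat, _, _ = _logrank_core(times, events, labels, 2)
            hits += stat >= obs_stat - 1e-12
            total += 1
        exact_p = hits / total
        groups = [
            (times[obs_labels == 0], events[obs_labels == 0]),
            (times[obs_labels == 1], events[obs_labels == 1]),
        ]
        res = logrank(groups, method="permutation", n_permutations=10000, seed=42)
        mc_err = 3 * np.sqrt(exact_p * (1 - exact_p) / 10000) + 2e-4
        assert abs(res.p_value - exact_p) <= mc_err

    def test_pairwise_covers_all_pairs(self, rng):
        g = [
            (rng.exponential(40, 20), np.ones(20, dtype=int)),
            (rng.exponential(25, 20), np.ones(20, dtype=int)),
            (rng.exponential(55, 20), np.ones(20, dtype=int)),
        ]
        out = pairwise_logrank(g, ["a", "b", "c"])
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_statistic_grows_with_hazard_gap(self):
        """Enlarging the planted hazard gap never decreases the average
        statistic over a grid of effect sizes."""
        means = []
        for ratio in (1.0, 2.0, 4.0):
            stats_at = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                t1 = rng.exponential(50, 40)
                t2 = rng.exponential(50 / ratio, 40)
                res = logrank([(t1, np.ones(40, int)), (t2, np.ones(40, int))])
                stats_at.append(res.statistic)
            means.append(np.mean(stats_at))
        assert means[0] <= means[1] <= means[2]
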