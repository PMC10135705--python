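"""Kaplan-Meier estimator and logrank test against hand computations,
frozen reference-library fixtures, and their sampling properties."""

import json
from pathlib import Path

import numpy as np
import pytest

from cdr3comp import SurvivalRecord, km_estimate, logrank_test
from cdr3comp.exceptions import UndefinedStatisticError, ValidationError

FIXTURES = Path(__file__).parent / "data" / "logrank_fixtures.json"


def subjects(times, events, prefix="s"):
    return [SurvivalRecord(f"{prefix}{i}", t, e)
            for i, (t, e) in enumerate(zip(times, events))]


class TestKaplanMeier:
    def test_hand_worked_example(self):
        # t=1: n=3, d=1 -> 2/3; censored at 2 shrinks the risk set;
        # t=3: n=1, d=1 -> 0
        curve = km_estimate(subjects([1, 2, 3], [1, 0, 1]))
        assert curve.event_times == (1.0, 3.0)
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == pytest.approx(0.0)
        assert curve.at_risk == (3, 1)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate(subjects([5, 10, 15], [0, 0, 0]))
        assert curve.event_times == ()
        assert curve.survival_at(100.0) == 1.0

    def test_single_event_drops_to_zero(self):
        curve = km_estimate(subjects([5], [1]))
        assert curve.survival_at(5.0) == 0.0

    def test_censoring_tied_with_event_counted_at_risk(self):
        # events-first convention: the subject censored at t=2 is still at
        # risk for the event at t=2
        curve = km_estimate(subjects([2, 2, 4], [1, 0, 1]))
        assert curve.at_risk[0] == 3
        assert curve.survival[0] == pytest.approx(2 / 3)

    def test_non_increasing(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 40))
            recs = subjects(rng.exponential(10, n), rng.integers(0, 2, n))
            curve = km_estimate(recs)
            assert all(a >= b - 1e-12
                       for a, b in zip(curve.survival, curve.survival[1:]))

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, 50)
        curve = km_estimate(subjects(times, np.ones(50, dtype=int)))
        for t in [1.0, 5.0, 10.0, 25.0]:
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalRecord("s", -1.0, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups_null(self):
        group = subjects([1, 3, 5, 7, 9], [1, 1, 0, 1, 0])
        res = logrank_test(group, group)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_hand_computation(self):
        """Six subjects, events at 1,2,3 vs 10,20,30: the O/E/Var table
        evaluated by hand gives chi2 = (3 - 1.15)^2 / 0.6775."""
        a = subjects([1, 2, 3], [1, 1, 1], "a")
        b = subjects([10, 20, 30], [1, 1, 1], "b")
        res = logrank_test(a, b)
        expected_e_a = 3 / 6 + 2 / 5 + 1 / 4  # b contributes 0 while a remains
        expected_var = (3 * 3) / 36 + (2 * 3) / 25 + (1 * 3) / 16
        assert res.expected[0] == pytest.approx(expected_e_a)
        assert res.chi_square == pytest.approx(
            (3 - expected_e_a) ** 2 / expected_var)

    def test_symmetric_in_groups(self, rng):
        a = subjects(rng.exponential(10, 20), rng.integers(0, 2, 20), "a")
        b = subjects(rng.exponential(20, 15), rng.integers(0, 2, 15), "b")
        ab = logrank_test(a, b)
        ba = logrank_test(b, a)
        assert ab.chi_square == pytest.approx(ba.chi_square, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_expected_counts_sum_to_observed_events(self, rng):
        a = subjects(rng.exponential(10, 25), rng.integers(0, 2, 25), "a")
        b = subjects(rng.exponential(15, 25), rng.integers(0, 2, 25), "b")
        res = logrank_test(a, b)
        assert sum(res.expected) == pytest.approx(sum(res.observed))

    def test_no_events_undefined(self):
        a = subjects([1, 2], [0, 0], "a")
        b = subjects([3, 4], [0, 0], "b")
        with pytest.raises(UndefinedStatisticError):
            logrank_test(a, b)

    def test_matches_frozen_reference_fixtures(self):
        """Chi-square agrees to 1e-8 with a reference survival library on
        50 random censored cohorts (values frozen from that library)."""
        with open(FIXTURES) as fh:
            frozen = json.load(fh)
        rng = np.random.default_rng(frozen["seed"])
        for fix in frozen["fixtures"]:
            na = int(rng.integers(5, 31))
            nb = int(rng.integers(5, 31))
            assert (na, nb) == (fix["n_a"], fix["n_b"])
            ta = rng.exponential(12.0, size=na)
            tb = rng.exponential(12.0 * rng.uniform(0.5, 2.0), size=nb)
            ca = rng.uniform(0, 40.0, size=na)
            cb = rng.uniform(0, 40.0, size=nb)
            ea = (ta <= ca).astype(int)
            tb_obs = np.minimum(tb, cb)
            ta_obs = np.minimum(ta, ca)
            eb = (tb <= cb).astype(int)
            res = logrank_test(subjects(ta_obs, ea, "a"), subjects(tb_obs, eb, "b"))
            assert res.chi_square == pytest.approx(fix["chi_square"], abs=1e-8)

    def test_live_cross_check_against_lifelines(self, rng):
        """Independent dual-route check on fresh cohorts, not the frozen ones."""
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        for _ in range(5):
            ta = rng.exponential(10, 30)
            tb = rng.exponential(18, 25)
            ea = rng.integers(0, 2, 30)
            eb = rng.integers(0, 2, 25)
            if ea.sum() + eb.sum() == 0:
                continue
            mine = logrank_test(subjects(ta, ea, "a"), subjects(tb, eb, "b"))
            ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea,
                                               event_observed_B=eb)
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-8)


class TestSamplingProperties:
    def test_type_one_error_near_alpha(self):
        """Under identical exponential hazards the test rejects at the
        nominal 5% rate, within binomial tolerance over 200 replicates."""
        rng = np.random.default_rng(777)
        rejections = 0
        n = 60
        for _ in range(200):
            a = subjects(rng.exponential(10, n), np.ones(n, dtype=int), "a")
            b = subjects(rng.exponential(10, n), np.ones(n, dtype=int), "b")
            if logrank_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / 200 <= 0.09

    def test_power_at_hazard_ratio_two(self):
        """At hazard ratio 2, n=100 per group, no censoring, power
        comfortably exceeds 0.80."""
        rng = np.random.default_rng(778)
        rejections = 0
        n = 100
        for _ in range(200):
            a = subjects(rng.exponential(10, n), np.ones(n, dtype=int), "a")
            b = subjects(rng.exponential(5, n), np.ones(n, dtype=int), "b")
            if logrank_test(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.80
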