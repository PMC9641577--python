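"""Validation metrics: O:E, concordance, Royston's D, calibration curves."""

import warnings

import numpy as np
import pytest

from crisk.performance import (calibration_curve, harrell_c,
                               observed_expected_ratio,
                               per_practice_performance, r2_from_d,
                               royston_d, KAPPA_SQ, SIGMA_SQ)


def brute_force_c(theta, pred):
    num, den = 0.0, 0
    n = len(theta)
    for i in range(n):
        for j in range(i + 1, n):
            if theta[i] == theta[j]:
                continue
            den += 1
            hi, lo = (i, j) if theta[i] > theta[j] else (j, i)
            if pred[hi] > pred[lo]:
                num += 1.0
            elif pred[hi] == pred[lo]:
                num += 0.5
    return num / den


class TestObservedExpected:
    def test_arithmetic(self):
        theta = np.full(10, 0.10)
        pred = np.full(10, 0.05)
        oe, _ = observed_expected_ratio(theta, pred)
        assert oe == pytest.approx(2.0)

    def test_exact_unity_when_predictions_match_means(self, rng):
        theta = rng.random(100)
        pred = np.full(100, theta.mean())
        assert observed_expected_ratio(theta, pred)[0] == pytest.approx(1.0)

    def test_reorder_invariance_and_scaling(self, rng):
        theta, pred = rng.random(50), rng.random(50) * 0.3
        oe1 = observed_expected_ratio(theta, pred)[0]
        perm = rng.permutation(50)
        assert observed_expected_ratio(theta[perm], pred[perm])[0] \
            == pytest.approx(oe1)
        assert observed_expected_ratio(theta, 2 * pred)[0] \
            == pytest.approx(oe1 / 2)

    def test_true_model_calibrated_in_the_large(self, calibration_study):
        from crisk.pseudo import grouped_pseudovalues
        _, outcomes, lp, true_risk, _ = calibration_study
        pv = grouped_pseudovalues(outcomes["time"], outcomes["event"], lp,
                                  10.0, n_groups=50)
        oe, _ = observed_expected_ratio(pv, true_risk[10.0])
        assert 0.95 < oe < 1.05

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            observed_expected_ratio(np.array([0.1]), np.array([0.0]))


class TestHarrellC:
    def test_spec_toy_example(self):
        theta = np.array([0.0, 0.0, 1.0, 1.0])
        pred = np.array([0.1, 0.4, 0.3, 0.2])
        assert harrell_c(theta, pred)[0] == \
            pytest.approx(brute_force_c(theta, pred))

    def test_perfect_ranking(self, rng):
        theta = rng.random(200)
        assert harrell_c(theta, theta * 2 + 1)[0] == 1.0

    def test_random_predictions_near_half(self, rng):
        theta = (rng.random(10_000) < 0.2).astype(float)
        pred = rng.random(10_000)
        c, se = harrell_c(theta, pred)
        assert abs(c - 0.5) < 0.02

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 60))
            theta = rng.normal(size=n).round(1)
            pred = rng.normal(size=n).round(1)
            c, _ = harrell_c(theta, pred)
            assert c == pytest.approx(brute_force_c(theta, pred), abs=1e-14)

    def test_monotone_transform_invariance(self, rng):
        theta = rng.normal(size=300)
        pred = rng.random(300)
        c1, _ = harrell_c(theta, pred)
        c2, _ = harrell_c(theta, np.exp(3 * pred) - 1)
        assert c1 == pytest.approx(c2, abs=1e-14)

    def test_constant_predictions_give_half_with_warning(self, rng):
        with pytest.warns(UserWarning, match="identical"):
            c, _ = harrell_c(rng.random(20), np.full(20, 0.3))
        assert c == 0.5


class TestRoystonD:
    def test_zero_d_gives_zero_r2(self):
        assert r2_from_d(0.0) == 0.0

    def test_closed_form_value(self):
        # D = 1.597: R2 = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2) ~ 0.378
        d = 1.597
        expected = (d ** 2 / KAPPA_SQ) / (SIGMA_SQ + d ** 2 / KAPPA_SQ)
        assert r2_from_d(d) == pytest.approx(expected, abs=1e-15)
        assert r2_from_d(d) == pytest.approx(0.378, abs=5e-3)

    def test_r2_increasing_in_magnitude(self):
        ds = np.linspace(0, 5, 30)
        r2 = [r2_from_d(d) for d in ds]
        assert np.all(np.diff(r2) > 0)
        assert r2[-1] < 1.0
        assert r2_from_d(-2.0) == r2_from_d(2.0)

    def test_null_lp_gives_small_d(self, rng):
        theta = (rng.random(4000) < 0.3).astype(float)
        lp = rng.normal(size=4000)
        d, se, r2 = royston_d(theta, lp)
        assert abs(d) < 3 * se
        assert r2 < 0.02

    def test_discriminating_lp_gives_positive_d(self, calibration_study):
        from crisk.pseudo import grouped_pseudovalues
        _, outcomes, lp, _, _ = calibration_study
        pv = grouped_pseudovalues(outcomes["time"], outcomes["event"], lp,
                                  10.0, n_groups=50)
        d, se, r2 = royston_d(pv, lp)
        assert d > 10 * se
        assert 0.0 < r2 < 1.0

    def test_constant_lp_warns(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            d, _, r2 = royston_d(rng.random(50), np.ones(50))
        assert d == 0.0 and r2 == 0.0


class TestCalibrationCurve:
    def test_group_points_are_ordered_means(self, rng):
        theta = rng.random(500)
        pred = rng.random(500)
        cc = calibration_curve(theta, pred, n_groups=10)
        assert len(cc.group_pred) == 10
        assert np.all(np.diff(cc.group_pred) > 0)
        assert np.all((cc.group_pred >= 0) & (cc.group_pred <= 1))

    def test_constant_predictions_single_point(self, rng):
        theta = rng.random(50)
        pred = np.full(50, 0.2)
        cc = calibration_curve(theta, pred, n_groups=1)
        assert cc.curve_x[0] == pytest.approx(0.2)
        assert cc.curve_y[0] == pytest.approx(theta.mean())

    def test_group_points_independent_of_smoother_span(self, rng):
        theta, pred = rng.random(300), rng.random(300)
        c1 = calibration_curve(theta, pred, frac=0.3)
        c2 = calibration_curve(theta, pred, frac=0.9)
        assert np.allclose(c1.group_pred, c2.group_pred)
        assert np.allclose(c1.group_obs, c2.group_obs)

    def test_more_groups_than_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            calibration_curve(rng.random(5), rng.random(5), n_groups=10)


class TestPerPractice:
    @staticmethod
    def _inputs(rng, n=400, n_practices=1):
        practice = rng.integers(0, n_practices, n)
        events = rng.choice([0, 1, 2], n, p=[0.4, 0.4, 0.2])
        lp = rng.normal(size=n)
        theta = (events == 1) + rng.normal(0, 0.05, n) + 0.3 * lp
        pred = 1 / (1 + np.exp(-lp))
        return practice, events, theta, pred, lp

    def test_single_practice_matches_overall(self, rng):
        practice, events, theta, pred, lp = self._inputs(rng)
        metrics, excl = per_practice_performance(practice, events, theta,
                                                 pred, lp)
        assert len(metrics) == 1 and len(excl) == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert metrics["oe"].iloc[0] == pytest.approx(
                observed_expected_ratio(theta, pred)[0])
            assert metrics["c"].iloc[0] == pytest.approx(
                harrell_c(theta, pred)[0])
            assert metrics["d"].iloc[0] == pytest.approx(
                royston_d(theta, lp)[0])

    def test_replicated_practice_gives_identical_rows(self, rng):
        practice, events, theta, pred, lp = self._inputs(rng, n=200)
        two = np.concatenate([np.zeros(200, int), np.ones(200, int)])
        metrics, _ = per_practice_performance(
            two, np.tile(events, 2), np.tile(theta, 2), np.tile(pred, 2),
            np.tile(lp, 2))
        assert np.allclose(metrics.loc[0, ["oe", "c", "d"]].astype(float),
                           metrics.loc[1, ["oe", "c", "d"]].astype(float))

    def test_minimum_data_rules_exclude(self, rng):
        practice = np.concatenate([np.zeros(100, int), np.ones(10, int)])
        events = np.concatenate([rng.choice([0, 1], 100), np.zeros(10, int)])
        theta = rng.random(110)
        pred = rng.random(110)
        lp = rng.normal(size=110)
        metrics, excl = per_practice_performance(practice, events, theta,
                                                 pred, lp)
        assert list(excl["practice_id"]) == [1]
        assert set(metrics.index) == {0}
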