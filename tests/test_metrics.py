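import numpy as np
import pytest
from sksurv.metrics import brier_score as sksurv_brier
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from funsurf.metrics import (
    UndefinedMetricError,
    brier_score,
    calibration_table,
    censoring_survival,
    censoring_weights,
    time_dependent_auc,
)


def _random_survival(n=50, seed=0, censor_frac=0.4):
    rng = np.random.default_rng(seed)
    t = rng.exponential(20, n).round(3) + 0.001  # continuous, distinct
    c = rng.exponential(20 / censor_frac * (1 - censor_frac), n).round(3) + 0.002
    times = np.minimum(t, c)
    events = t <= c
    risk = rng.random(n)
    return times, events, risk


class TestCensoringWeights:
    def test_no_censoring_gives_unit_weights(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=bool)
        np.testing.assert_array_equal(
            censoring_weights(times, events, 2.5), np.ones(4)
        )

    def test_hand_computed_toy(self, toy_survival):
        """G drops at censorings 4, 7, 11: G=[1, .8, .5333, 0]; horizon 8."""
        times, events = toy_survival
        w = censoring_weights(times, events, 8.0)
        expected = np.array([1.0, 0.0, 1 / 0.8, 0.0, 1.875, 1.875])
        np.testing.assert_allclose(w, expected, rtol=1e-12)

    def test_matches_lifelines_censoring_km(self, toy_survival):
        from lifelines import KaplanMeierFitter

        times, events = toy_survival
        jt, gv = censoring_survival(times, events)
        kmf = KaplanMeierFitter().fit(times, ~events)
        for u, g in zip(jt, gv):
            assert g == pytest.approx(float(kmf.predict(u)), abs=1e-12)

    def test_all_censored_before_horizon_is_error(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.zeros(3, dtype=bool)
        with pytest.raises(UndefinedMetricError):
            censoring_weights(times, events, 10.0)


class TestTimeDependentAuc:
    def test_perfect_separation_no_censoring(self):
        times = np.array([2.0, 3.0, 20.0, 30.0])
        events = np.ones(4, dtype=bool)
        risk = np.array([0.9, 0.8, 0.2, 0.1])
        assert time_dependent_auc(risk, times, events, 10.0) == 1.0

    def test_matches_brute_force_pairwise(self):
        """Weighted double loop over all case/control pairs, ties count 1/2."""
        times, events, risk = _random_survival(n=50, seed=1)
        horizon = 15.0
        w = censoring_weights(times, events, horizon)
        num = den = 0.0
        for i in range(50):
            if not (times[i] <= horizon and events[i]):
                continue
            for j in range(50):
                if times[j] <= horizon:
                    continue
                pw = w[i] * w[j]
                den += pw
                if risk[i] > risk[j]:
                    num += pw
                elif risk[i] == risk[j]:
                    num += 0.5 * pw
        oracle = num / den
        got = time_dependent_auc(risk, times, events, horizon)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_risk_negation_flips_auc(self):
        times, events, risk = _random_survival(n=60, seed=2)
        a = time_dependent_auc(risk, times, events, 15.0)
        b = time_dependent_auc(-risk, times, events, 15.0)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sksurv_uno_auc(self):
        times, events, risk = _random_survival(n=200, seed=3)
        horizon = 15.0
        y = Surv.from_arrays(events, times)
        expected, _ = cumulative_dynamic_auc(y, y, risk, [horizon])
        got = time_dependent_auc(risk, times, events, horizon)
        assert got == pytest.approx(expected[0], abs=1e-8)

    def test_no_cases_is_error(self):
        times = np.array([10.0, 20.0, 30.0])
        events = np.ones(3, dtype=bool)
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc(np.ones(3), times, events, 5.0)


class TestBrierScore:
    def test_reduces_to_mse_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(20, 100) + 0.01
        events = np.ones(100, dtype=bool)
        surv = rng.random(100)
        horizon = 15.0
        d = (times <= horizon).astype(float)
        mse = np.mean((d - (1 - surv)) ** 2)
        assert brier_score(surv, times, events, horizon) == pytest.approx(
            mse, abs=1e-12
        )

    def test_perfect_predictions_score_zero(self):
        times = np.array([2.0, 3.0, 20.0, 30.0])
        events = np.ones(4, dtype=bool)
        surv = np.array([0.0, 0.0, 1.0, 1.0])
        assert brier_score(surv, times, events, 10.0) == 0.0

    def test_constant_half_gives_quarter(self):
        times = np.array([2.0, 3.0, 20.0, 30.0])
        events = np.ones(4, dtype=bool)
        assert brier_score(np.full(4, 0.5), times, events, 10.0) == pytest.approx(
            0.25, abs=1e-12
        )

    def test_agrees_with_sksurv_under_censoring(self):
        times, events, risk = _random_survival(n=200, seed=5)
        surv = 1 - risk
        horizon = 15.0
        y = Surv.from_arrays(events, times)
        _, expected = sksurv_brier(y, y, surv[:, None], [horizon])
        got = brier_score(surv, times, events, horizon)
        assert got == pytest.approx(expected[0], abs=1e-8)

    def test_out_of_range_predictions_rejected(self):
        times = np.array([2.0, 20.0])
        events = np.ones(2, dtype=bool)
        with pytest.raises(ValueError):
            brier_score(np.array([1.2, 0.5]), times, events, 10.0)


class TestCalibrationTable:
    def test_bins_partition_subjects(self):
        times, events, risk = _random_survival(n=200, seed=6)
        table = calibration_table(risk, times, events, 15.0, n_groups=5)
        assert table["n"].sum() == 200

    def test_constant_predictions_collapse_to_single_bin(self):
        times, events, _ = _random_survival(n=50, seed=7)
        table = calibration_table(np.full(50, 0.3), times, events, 15.0)
        assert len(table) == 1
        assert table["n"].iloc[0] == 50

    def test_calibrated_predictions_match_observed(self):
        """Predictions equal to the true event probability land within
        Monte-Carlo error of the Kaplan-Meier observed rates."""
        rng = np.random.default_rng(8)
        n = 4000
        lam = rng.uniform(0.01, 0.12, n)  # exponential hazards
        times = rng.exponential(1 / lam)
        events = np.ones(n, dtype=bool)
        horizon = 12.0
        pred = 1 - np.exp(-lam * horizon)
        table = calibration_table(pred, times, events, horizon, n_groups=5)
        gap = (table["mean_predicted"] - table["observed"]).abs()
        se = np.sqrt(
            table["mean_predicted"] * (1 - table["mean_predicted"]) / table["n"]
        )
        assert (gap < 3 * se).all()

    def test_too_few_groups_rejected(self):
        times, events, risk = _random_survival(n=30, seed=9)
        with pytest.raises(ValueError):
            calibration_table(risk, times, events, 15.0, n_groups=1)
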